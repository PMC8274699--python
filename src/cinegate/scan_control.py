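"""Pulse-sequence looping structure as a discrete-time state machine.

In steady-state-maintained (tSSM) mode the scanner clock ticks at a constant
TR forever: each tick is either a gate-evaluation element or one line of a
CINE block.  The gate line is sampled once per TR at tick start; a high level
launches an NE-frame CINE block for the next pending phase encode.  When more
than ``breath_count_threshold`` consecutive gate-evaluation ticks elapse
without a trigger a breath (or missed R-wave) is declared and the
``n_reacquire`` most recently kept blocks are re-queued, to be re-acquired at
the next available opportunity once the breath completes.  The scan ends when
every phase-encode index has exactly one kept block.

Because the gate is evaluated once per TR, a trigger arriving with uniform
phase relative to the TR clock starts its first frame with a uniform delay of
up to one TR — mean 0.5*TR — which is the trigger jitter this module can
quantify.

Comparison modes:

* cCRT — conventional triggering: RF only during CINE blocks; scanning
  suspends between blocks and during breaths (mixed effective TR).
* DG — double gating: an RF block runs after *every* heartbeat, breaths
  included, but data are kept only for triggers inside the respiratory
  acquire window; a hiatus separates block end from the next beat.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError, ScanTimeoutError
from .ttl import TTLSignal

__all__ = ["ScanParams", "CineBlock", "AcquisitionSchedule",
           "run_scan", "run_scan_ccrt", "run_scan_dg", "run_localiser",
           "trigger_jitter_stats", "scan_time_summary", "centre_out_order"]

STATUS_KEPT = "kept"
STATUS_REACQUIRED = "discarded_reacquired"


@dataclass
class ScanParams:
    """Sequence-level dials (defaults mirror the high-throughput CINE protocol)."""

    tr: float = 4.0
    n_frames: int = 20               # NE: CINE frames per block
    n_phase_encodes: int = 128
    breath_count_threshold: int = 25  # strict '>': declare on tick 26
    n_reacquire: int = 2
    mode: str = "tSSM"               # tSSM | cCRT | DG
    localiser_segments: int = 4      # phase encodes per R-wave in localiser mode

    def __post_init__(self):
        if self.tr <= 0:
            raise InvalidParameterError("tr must be > 0")
        for name in ("n_frames", "n_phase_encodes", "breath_count_threshold",
                     "n_reacquire", "localiser_segments"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be a positive count")
        if self.mode not in ("tSSM", "cCRT", "DG"):
            raise InvalidParameterError("mode must be tSSM, cCRT or DG")

    @property
    def declared_breath_latency(self) -> float:
        """Latency from trigger loss to breath declaration: threshold * TR (ms)."""
        return self.breath_count_threshold * self.tr

    @property
    def cine_block_duration(self) -> float:
        """Envelope of one CINE block: NE * TR (ms)."""
        return self.n_frames * self.tr


@dataclass
class CineBlock:
    phase_encode_index: int
    trigger_time: float
    frame_times: np.ndarray
    status: str = STATUS_KEPT
    truncated: bool = False


@dataclass
class AcquisitionSchedule:
    """Per-block log of one simulated scan."""

    blocks: list[CineBlock]
    breath_declarations: list[float]
    rf_pulse_times: np.ndarray
    total_duration: float
    start_time: float
    mode: str

    @property
    def kept_blocks(self) -> list[CineBlock]:
        return [b for b in self.blocks if b.status == STATUS_KEPT]

    @property
    def reacquired_blocks(self) -> list[CineBlock]:
        return [b for b in self.blocks if b.status == STATUS_REACQUIRED]

    def to_jsonl(self, path) -> None:
        import json
        with open(path, "w") as fh:
            for b in self.blocks:
                fh.write(json.dumps({
                    "phase_encode_index": b.phase_encode_index,
                    "trigger_time_ms": b.trigger_time,
                    "frame_times_ms": b.frame_times.tolist(),
                    "status": b.status,
                    "truncated": b.truncated,
                }) + "\n")


def centre_out_order(n: int) -> list[int]:
    """Phase-encode ordering by |index - n/2|, ties low-index-first."""
    return sorted(range(n), key=lambda i: (abs(i - n // 2), i))


def _finalize(blocks, declarations, rf, t0, mode) -> AcquisitionSchedule:
    rf_arr = np.asarray(rf, dtype=float)
    last = max((float(b.frame_times[-1]) for b in blocks), default=t0)
    return AcquisitionSchedule(
        blocks=blocks,
        breath_declarations=declarations,
        rf_pulse_times=rf_arr,
        total_duration=last - t0,
        start_time=t0,
        mode=mode,
    )


def run_scan(cr_ttl: TTLSignal, params: ScanParams,
             start_time: float | None = None,
             encode_order: list[int] | None = None) -> AcquisitionSchedule:
    """tSSM scan: constant-TR tick loop driven by the combined gate level.

    Raises :class:`ScanTimeoutError` if the gate stream ends before every
    phase encode is kept.
    """
    gate = cr_ttl.normalized()
    if gate.starts.size and np.any((gate.ends - gate.starts) < params.tr):
        import logging
        logging.getLogger(__name__).warning(
            "run_scan: gate pulses shorter than TR may be missed by tick sampling")
    t0 = float(gate.t0 if start_time is None else start_time)
    t_end = float(gate.t1)
    queue = deque(encode_order if encode_order is not None
                  else range(params.n_phase_encodes))
    expected = set(queue)

    blocks: list[CineBlock] = []
    kept: list[CineBlock] = []
    declarations: list[float] = []
    rf: list[float] = []
    consecutive = 0
    # no declaration before the first block: the count threshold exists to
    # invalidate previously acquired data, and there is none yet
    declared = True
    confirmed = False
    t = t0
    # after the queue empties, gate evaluation continues until the next
    # trigger confirms that no breath invalidated the final blocks (a breath
    # in that window declares and re-queues them as anywhere else)
    while queue or not confirmed:
        if t > t_end:
            if queue:
                raise ScanTimeoutError(
                    f"gate signal exhausted at {t_end:.1f} ms with "
                    f"{len(queue)} phase encodes pending", missing=sorted(queue))
            break  # stream ended while awaiting confirmation
        if gate.level_at(t):
            if not queue:
                confirmed = True
                continue
            idx = queue.popleft()
            frames = t + params.tr * np.arange(params.n_frames)
            block = CineBlock(phase_encode_index=idx, trigger_time=t,
                              frame_times=frames)
            blocks.append(block)
            kept.append(block)
            rf.extend(frames.tolist())
            t += params.tr * params.n_frames
            consecutive = 0
            declared = False
        else:
            rf.append(t)
            t += params.tr
            consecutive += 1
            if consecutive > params.breath_count_threshold and not declared:
                declarations.append(t - params.tr)
                declared = True
                requeue = kept[-params.n_reacquire:]
                for b in requeue:
                    b.status = STATUS_REACQUIRED
                for b in reversed(requeue):
                    queue.appendleft(b.phase_encode_index)
                kept = kept[:len(kept) - len(requeue)]
    sched = _finalize(blocks, declarations, rf, t0, "tSSM")
    _assert_complete(sched, expected)
    return sched


def _qualifying_onsets(ecg_ttl: TTLSignal, resp_acquire_ttl: TTLSignal | None):
    onsets = ecg_ttl.normalized().onsets
    if resp_acquire_ttl is None:
        return onsets, np.ones(onsets.size, dtype=bool)
    acq = resp_acquire_ttl.normalized()
    ok = np.array([bool(acq.level_at(t)) for t in onsets])
    return onsets, ok


def run_scan_ccrt(ecg_ttl: TTLSignal, resp_acquire_ttl: TTLSignal,
                  params: ScanParams) -> AcquisitionSchedule:
    """Conventional cardio-respiratory triggering.

    Each qualifying R-wave trigger (inside the respiratory acquire window,
    after the previous block has completed) starts an NE-frame block with RF
    only during the block; no RF during waits or breaths, no re-acquisition.
    """
    onsets, ok = _qualifying_onsets(ecg_ttl, resp_acquire_ttl)
    queue = deque(range(params.n_phase_encodes))
    expected = set(queue)
    blocks: list[CineBlock] = []
    rf: list[float] = []
    ready = -np.inf
    t0 = float(onsets[0]) if onsets.size else 0.0
    for onset, good in zip(onsets, ok):
        if not queue:
            break
        if not good or onset < ready:
            continue
        idx = queue.popleft()
        frames = onset + params.tr * np.arange(params.n_frames)
        blocks.append(CineBlock(idx, float(onset), frames))
        rf.extend(frames.tolist())
        ready = onset + params.cine_block_duration
    sched = _finalize(blocks, [], rf, t0, "cCRT")
    _assert_complete(sched, expected, context="cCRT: trigger stream exhausted")
    return sched


def run_scan_dg(ecg_ttl: TTLSignal, params: ScanParams,
                resp_acquire_ttl: TTLSignal | None = None) -> AcquisitionSchedule:
    """Double gating: an RF block after every heartbeat, data kept only for
    triggers inside the respiratory acquire window.

    If the next beat arrives before a block completes (R-R < NE*TR) the block
    is truncated at the new trigger and flagged.
    """
    onsets, ok = _qualifying_onsets(ecg_ttl, resp_acquire_ttl)
    queue = deque(range(params.n_phase_encodes))
    expected = set(queue)
    blocks: list[CineBlock] = []
    rf: list[float] = []
    ready = -np.inf
    t0 = float(onsets[0]) if onsets.size else 0.0
    for i, (onset, good) in enumerate(zip(onsets, ok)):
        if not queue:
            break
        if onset < ready:
            continue
        frames = onset + params.tr * np.arange(params.n_frames)
        next_onset = onsets[i + 1] if i + 1 < onsets.size else np.inf
        truncated = False
        if next_onset < frames[-1]:
            frames = frames[frames < next_onset]
            truncated = True
            if frames.size == 0:
                continue
        if good:
            idx = queue.popleft()
            blocks.append(CineBlock(idx, float(onset), frames, truncated=truncated))
        rf.extend(frames.tolist())
        ready = frames[-1] + params.tr
    sched = _finalize(blocks, [], rf, t0, "DG")
    _assert_complete(sched, expected, context="DG: trigger stream exhausted")
    return sched


def run_localiser(cr_ttl: TTLSignal, params: ScanParams) -> AcquisitionSchedule:
    """Segmented localiser: ``localiser_segments`` centre-out phase encodes
    (one TR each) acquired per trigger instead of a full CINE block."""
    gate = cr_ttl.normalized()
    order = deque(centre_out_order(params.n_phase_encodes))
    expected = set(order)
    blocks: list[CineBlock] = []
    rf: list[float] = []
    t = float(gate.t0)
    t_end = float(gate.t1)
    while order:
        if t > t_end:
            raise ScanTimeoutError("gate exhausted during localiser",
                                   missing=sorted(order))
        if gate.level_at(t):
            take = min(params.localiser_segments, len(order))
            seg = [order.popleft() for _ in range(take)]
            for k, idx in enumerate(seg):
                ft = np.array([t + k * params.tr])
                blocks.append(CineBlock(idx, t, ft))
                rf.append(float(ft[0]))
            t += params.tr * len(seg)
        else:
            rf.append(t)
            t += params.tr
    sched = _finalize(blocks, [], rf, gate.t0, "localiser")
    _assert_complete(sched, expected)
    return sched


def _assert_complete(sched: AcquisitionSchedule, expected: set,
                     context: str = "scan incomplete"):
    kept = [b.phase_encode_index for b in sched.kept_blocks]
    missing = sorted(expected - set(kept))
    if missing or len(kept) != len(set(kept)):
        raise ScanTimeoutError(
            f"{context}: phase encodes missing or duplicated: {missing[:10]}",
            missing=missing)


@dataclass
class JitterSummary:
    delays: np.ndarray
    tr: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.delays))

    @property
    def mean_in_tr(self) -> float:
        return self.mean / self.tr

    def histogram(self, bins: int = 10):
        return np.histogram(self.delays, bins=bins, range=(0.0, self.tr))


def trigger_jitter_stats(schedules, ttl_signals, tr: float) -> JitterSummary:
    """First-frame delay after each gate onset, pooled over schedules.

    For every block, the delay is first frame time minus the most recent TTL
    onset.  With triggers asynchronous to the TR clock the delays are uniform
    over one TR with mean 0.5*TR.
    """
    if not isinstance(schedules, (list, tuple)):
        schedules = [schedules]
        ttl_signals = [ttl_signals]
    delays = []
    for sched, ttl in zip(schedules, ttl_signals):
        onsets = ttl.normalized().onsets
        for b in sched.blocks:
            i = np.searchsorted(onsets, b.trigger_time + 1e-9) - 1
            if i < 0:
                continue
            delays.append(b.frame_times[0] - onsets[i])
    if not delays:
        raise InvalidInputError("no blocks with a preceding TTL onset")
    return JitterSummary(delays=np.asarray(delays), tr=tr)


def scan_time_summary(schedule: AcquisitionSchedule) -> dict:
    """Bookkeeping totals of a completed schedule."""
    kept = schedule.kept_blocks
    if not kept:
        raise InvalidInputError("schedule holds no kept blocks")
    return {
        "total_duration_ms": schedule.total_duration,
        "kept_blocks": len(kept),
        "reacquired_blocks": len(schedule.reacquired_blocks),
        "breaths_declared": len(schedule.breath_declarations),
    }
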