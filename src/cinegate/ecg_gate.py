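"""Two-rate R-wave detection and cardio-respiratory gate combination.

The detector emulates the microprocessor's loop:

* IDLE — the voltage-scaled ECG is read at the base rate (1 kHz) and a
  2-point difference across a 4 ms lag (a high-pass that rejects the slow
  respiration-coupled voltage) is evaluated each sample; when it exceeds the
  arming threshold the R-wave onset is declared.
* ARMED — the raw voltage-scaled signal is read at the fast rate (10 kHz);
  the first sample lower than its predecessor marks the turning point, whose
  predecessor is the R-wave peak.  The cardiac gate pulse (dTTL_ECG, operator
  dial) is raised immediately and sampling reverts to the base rate.

Peak localisation via the turning point is independent of the signal
amplitude and DC level.  Re-arming is inhibited for a refractory period
(defaulting to the TTL duration).  Both paths are emulated by decimating a
single fast master trace, so the slow path sees every n-th sample of the fast
path.

The combined cardio-respiratory gate is the Boolean AND of the cardiac pulse
train with the respiratory acquire window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .physio import EventGroundTruth
from .trace import WaveformTrace
from .ttl import TTLSignal

__all__ = ["ECGGateConfig", "ECGGateResult", "LatencySummary",
           "ecg_difference", "detect_r_waves", "combine_gates",
           "detection_latency"]

log = logging.getLogger(__name__)


@dataclass
class ECGGateConfig:
    """Dials of the two-rate R-wave detector (all times in ms)."""

    base_sample_interval: float = 1.0
    diff_lag: float = 4.0
    arm_threshold: float = 0.08        # volts, on the lagged difference
    fast_sample_interval: float = 0.1
    ttl_duration: float = 16.0         # dTTL_ECG; > TR, < CINE block
    refractory: float | None = None    # defaults to ttl_duration
    arm_timeout: float = 20.0          # disarm if no turning point found (ms)

    def __post_init__(self):
        if self.base_sample_interval <= 0 or self.fast_sample_interval <= 0:
            raise InvalidParameterError("sample intervals must be > 0")
        if self.fast_sample_interval >= self.base_sample_interval:
            raise InvalidParameterError(
                "fast_sample_interval must be smaller than base_sample_interval")
        ratio = self.diff_lag / self.base_sample_interval
        if self.diff_lag <= 0 or abs(ratio - round(ratio)) > 1e-9:
            raise InvalidParameterError(
                "diff_lag must be a positive multiple of base_sample_interval")
        if self.ttl_duration <= 0:
            raise InvalidParameterError("ttl_duration must be > 0")
        if self.refractory is not None and self.refractory < 0:
            raise InvalidParameterError("refractory must be >= 0")
        if self.arm_timeout <= 0:
            raise InvalidParameterError("arm_timeout must be > 0")

    @property
    def effective_refractory(self) -> float:
        return self.ttl_duration if self.refractory is None else self.refractory


@dataclass
class ECGGateResult:
    """Detections, the cardiac gate line and bookkeeping traces."""

    detected_peaks: np.ndarray
    ecg_ttl: TTLSignal
    difference_trace: WaveformTrace
    mode_switch_times: list = field(default_factory=list)  # (arm ms, disarm ms)
    n_arm_timeouts: int = 0


@dataclass
class LatencySummary:
    """Per-beat latency of the cardiac gate against ground truth (ms)."""

    latencies: np.ndarray
    matched_true: np.ndarray
    n_missed: int
    n_false: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.latencies)) if self.latencies.size else float("nan")

    @property
    def max(self) -> float:
        return float(np.max(self.latencies)) if self.latencies.size else float("nan")


def _check_fast_trace(trace: WaveformTrace, cfg: ECGGateConfig):
    if abs(trace.sample_interval - cfg.fast_sample_interval) > 1e-9:
        raise InvalidInputError(
            f"trace sampled at {trace.sample_interval} ms; detector expects the "
            f"fast master rate {cfg.fast_sample_interval} ms")
    stride = cfg.base_sample_interval / cfg.fast_sample_interval
    if abs(stride - round(stride)) > 1e-9:
        raise InvalidInputError(
            "base_sample_interval must be an integer multiple of fast_sample_interval")
    return int(round(stride))


def ecg_difference(trace: WaveformTrace, cfg: ECGGateConfig) -> WaveformTrace:
    """Base-rate 2-point difference across ``diff_lag`` ms (leading samples 0).

    A drift of period P and amplitude A contributes at most
    2*pi*A*diff_lag/P volts, so the respiration-coupled voltage is largely
    eliminated while the R-wave's fast rising edge survives as a large step.
    """
    if trace.duration < cfg.diff_lag:
        raise InvalidInputError("trace shorter than diff_lag")
    base = trace if abs(trace.sample_interval - cfg.base_sample_interval) < 1e-9 \
        else trace.decimate(cfg.base_sample_interval)
    lag = int(round(cfg.diff_lag / cfg.base_sample_interval))
    if base.values.size <= lag:
        raise InvalidInputError("trace shorter than diff_lag")
    d = np.zeros_like(base.values)
    d[lag:] = base.values[lag:] - base.values[:-lag]
    return base.with_values(d, label=f"{trace.channel_label}_diff")


def detect_r_waves(trace: WaveformTrace, cfg: ECGGateConfig) -> ECGGateResult:
    """Run the two-rate detector state machine over a fast-rate ECG trace."""
    if cfg.arm_threshold <= 0:
        raise InvalidParameterError("arm_threshold must be > 0")
    stride = _check_fast_trace(trace, cfg)
    v = trace.values
    n = v.size
    dt = trace.sample_interval
    t0 = trace.start_time
    lag_fast = int(round(cfg.diff_lag / dt))          # lag in fast samples
    timeout_n = int(round(cfg.arm_timeout / dt))
    refractory = cfg.effective_refractory

    peaks: list[float] = []
    ttl_intervals: list[tuple[float, float]] = []
    switches: list[tuple[float, float]] = []
    n_timeouts = 0
    diff_vals: list[float] = []
    diff_times: list[float] = []

    next_ok_time = -np.inf   # earliest time re-arming is allowed
    m = lag_fast             # first base tick with a full lag available
    # align m to the base grid
    m += (-m) % stride
    while m < n:
        tm = t0 + m * dt
        d = v[m] - v[m - lag_fast]
        diff_vals.append(d)
        diff_times.append(tm)
        if d > cfg.arm_threshold and tm >= next_ok_time:
            # ARMED: walk fast samples for the turning point
            arm_time = tm
            j = m + 1
            found = False
            while j < n and j - m <= timeout_n:
                if v[j] < v[j - 1]:
                    k = j - 1
                    while k > m and v[k - 1] == v[k]:   # flat top: first plateau sample
                        k -= 1
                    peak_time = t0 + k * dt
                    onset = t0 + j * dt                 # TTL raised at detection instant
                    peaks.append(peak_time)
                    ttl_intervals.append((onset, onset + cfg.ttl_duration))
                    switches.append((arm_time, onset))
                    next_ok_time = onset + refractory
                    found = True
                    break
                j += 1
            if not found:
                n_timeouts += 1
                log.warning("ecg gate: armed at %.1f ms but no turning point "
                            "within %.0f ms; disarmed", arm_time, cfg.arm_timeout)
                switches.append((arm_time, t0 + min(j, n - 1) * dt))
            # revert to base sampling after the excursion
            m = j + ((-j) % stride)
        else:
            m += stride

    t_end = t0 + (n - 1) * dt
    ttl_intervals = [(s, min(e, t_end)) for s, e in ttl_intervals if s < t_end]
    ecg_ttl = TTLSignal.from_intervals(ttl_intervals, t0, t_end, label="dTTL_ECG")
    diff_trace = WaveformTrace(
        start_time=diff_times[0] if diff_times else t0,
        sample_interval=cfg.base_sample_interval,
        values=np.asarray(diff_vals) if diff_vals else np.zeros(1),
        channel_label=f"{trace.channel_label}_diff",
    )
    return ECGGateResult(
        detected_peaks=np.asarray(peaks),
        ecg_ttl=ecg_ttl,
        difference_trace=diff_trace,
        mode_switch_times=switches,
        n_arm_timeouts=n_timeouts,
    )


def combine_gates(ecg_ttl: TTLSignal, acquire_ttl: TTLSignal,
                  label: str = "cr_gate") -> TTLSignal:
    """Boolean AND of the cardiac pulses with the respiratory acquire window.

    Pulses straddling an acquire-window edge are truncated at the edge; pulses
    entirely inside a no-acquire period disappear.
    """
    return ecg_ttl.logical_and(acquire_ttl, label=label)


def detection_latency(result: ECGGateResult, truth: EventGroundTruth) -> LatencySummary:
    """Match TTL onsets to true (pre-amplifier) R-peaks and summarise latency.

    Each detection is matched to the nearest true peak within half the median
    R-R interval; unmatched true peaks count as misses, unmatched detections
    as false alarms.  Latency = TTL onset − true peak time.
    """
    true_peaks = truth.r_peak_times
    onsets = result.ecg_ttl.onsets
    if true_peaks.size == 0:
        raise InvalidInputError("ground truth contains no R peaks")
    if onsets.size == 0:
        return LatencySummary(np.empty(0), np.empty(0),
                              n_missed=int(true_peaks.size), n_false=0)
    rr = np.median(np.diff(true_peaks)) if true_peaks.size > 1 else np.inf
    half = rr / 2.0
    used = np.zeros(true_peaks.size, dtype=bool)
    lats, matched = [], []
    n_false = 0
    for onset in onsets:
        i = int(np.argmin(np.abs(true_peaks - onset)))
        if not used[i] and abs(true_peaks[i] - onset) <= half:
            used[i] = True
            lats.append(onset - true_peaks[i])
            matched.append(true_peaks[i])
        else:
            n_false += 1
    return LatencySummary(
        latencies=np.asarray(lats),
        matched_true=np.asarray(matched),
        n_missed=int(np.count_nonzero(~used)),
        n_false=n_false,
    )
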