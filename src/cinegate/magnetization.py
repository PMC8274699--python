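"""Longitudinal magnetization evolution through an acquisition schedule.

A perfectly spoiled gradient-echo (FLASH) model: between RF pulses the
longitudinal magnetization relaxes as

    Mz(t + d) = M0 + (Mz(t) - M0) * exp(-d / T1),

each pulse of flip angle a emits signal Mz * sin(a) * exp(-TE / T2*) and
leaves Mz * cos(a) behind.  Under constant-TR pulsing Mz converges
monotonically to the FLASH steady state M0 (1 - E1) / (1 - E1 cos a) with
E1 = exp(-TR / T1); this is why steady-state-maintained gating produces
frame intensities that depend only on M0, T1, T2*, flip angle and TR, while
conventional triggering and double gating pick up extra modulation from the
recovery gaps between imaging blocks.

Stability is summarised as coefficients of variation of the kept-frame
signals: short-term across the CINE frame dimension, long-term across the
first frames of repeated runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .scan_control import AcquisitionSchedule

__all__ = ["TissueParams", "SequenceParams", "MagnetizationRecord",
           "flash_steady_state", "evolve", "stability_metrics"]


@dataclass
class TissueParams:
    """Tissue properties (a.u. / ms); defaults loosely muscle-like at 7 T."""

    m0: float = 1.0
    t1: float = 1500.0
    t2_star: float = 20.0

    def __post_init__(self):
        if min(self.m0, self.t1, self.t2_star) <= 0:
            raise InvalidParameterError("m0, t1 and t2_star must be strictly positive")


@dataclass
class SequenceParams:
    """RF/readout parameters of the spoiled gradient-echo sequence."""

    flip_angle: float = 15.0   # degrees
    te: float = 1.89           # ms
    tr: float = 4.0            # ms

    def __post_init__(self):
        if not (0.0 < self.flip_angle <= 90.0):
            raise InvalidParameterError("flip_angle must lie in (0, 90] degrees")
        if self.te <= 0 or self.te >= self.tr:
            raise InvalidParameterError("need 0 < te < tr")


@dataclass
class MagnetizationRecord:
    """Mz before each pulse and the emitted signal, aligned to schedule blocks."""

    pulse_times: np.ndarray
    mz_before_pulse: np.ndarray
    signal: np.ndarray
    block_index: np.ndarray   # kept-block ordinal, -1 for non-frame pulses
    frame_index: np.ndarray   # frame within block, -1 for non-frame pulses

    def frame_signal_matrix(self, n_frames: int, skip_blocks: int = 0) -> np.ndarray:
        """(kept blocks - skipped) x n_frames matrix of frame signals."""
        blocks = np.unique(self.block_index[self.block_index >= 0])
        blocks = blocks[skip_blocks:]
        if blocks.size == 0:
            raise InvalidInputError("no kept blocks after burn-in skip")
        mat = np.full((blocks.size, n_frames), np.nan)
        for row, b in enumerate(blocks):
            sel = self.block_index == b
            mat[row, self.frame_index[sel]] = self.signal[sel]
        return mat

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({
            "block_index": self.block_index,
            "frame_index": self.frame_index,
            "time_ms": self.pulse_times,
            "mz_before": self.mz_before_pulse,
            "signal": self.signal,
        }).to_csv(path, index=False)


def flash_steady_state(tissue: TissueParams, seq: SequenceParams) -> float:
    """Closed-form steady-state Mz before each pulse at constant TR."""
    e1 = math.exp(-seq.tr / tissue.t1)
    a = math.radians(seq.flip_angle)
    return tissue.m0 * (1.0 - e1) / (1.0 - e1 * math.cos(a))


def evolve(schedule: AcquisitionSchedule, tissue: TissueParams,
           seq: SequenceParams, initial_mz: float | None = None) -> MagnetizationRecord:
    """Iterate the relax/pulse recursion over the schedule's RF pulse times.

    ``initial_mz`` defaults to M0 (fully relaxed at scan start); pass
    :func:`flash_steady_state` to start in the constant-TR steady state, e.g.
    to represent a scan preceded by a long run-in of steady-state pulsing.
    """
    times = np.sort(np.asarray(schedule.rf_pulse_times, dtype=float))
    if times.size == 0:
        empty = np.empty(0)
        return MagnetizationRecord(empty, empty.copy(), empty.copy(),
                                   empty.astype(int), empty.astype(int))
    a = math.radians(seq.flip_angle)
    sin_a, cos_a = math.sin(a), math.cos(a)
    echo = math.exp(-seq.te / tissue.t2_star)
    m0, t1 = tissue.m0, tissue.t1

    mz = m0 if initial_mz is None else float(initial_mz)
    mz_before = np.empty(times.size)
    sig = np.empty(times.size)
    prev_t = times[0]
    for i, t in enumerate(times):
        if t > prev_t:
            mz = m0 + (mz - m0) * math.exp(-(t - prev_t) / t1)
        mz_before[i] = mz
        sig[i] = mz * sin_a * echo
        mz *= cos_a
        prev_t = t

    # align pulses to kept-block frames
    block_idx = np.full(times.size, -1, dtype=int)
    frame_idx = np.full(times.size, -1, dtype=int)
    for b_ord, block in enumerate(b for b in schedule.blocks if b.status == "kept"):
        pos = np.searchsorted(times, block.frame_times)
        for f, p in enumerate(pos):
            if p < times.size and abs(times[p] - block.frame_times[f]) < 1e-6:
                block_idx[p] = b_ord
                frame_idx[p] = f
    return MagnetizationRecord(times, mz_before, sig, block_idx, frame_idx)


def stability_metrics(records, n_frames: int, skip_blocks: int = 0) -> dict:
    """Long- and short-term coefficients of variation of kept-frame signals.

    Short-term: CV across the CINE frame dimension of the per-frame mean
    signal (averaged over kept blocks), averaged over records.  Long-term:
    CV across records of the first-frame mean (needs >= 2 records).
    """
    if not isinstance(records, (list, tuple)):
        records = [records]
    short_cvs = []
    first_means = []
    for rec in records:
        mat = rec.frame_signal_matrix(n_frames, skip_blocks=skip_blocks)
        frame_means = np.nanmean(mat, axis=0)
        mu = float(np.mean(frame_means))
        if mu == 0:
            raise InvalidInputError("zero-mean signals: CV undefined")
        short_cvs.append(float(np.std(frame_means) / mu))
        first_means.append(float(np.nanmean(mat[:, 0])))
    out = {"short_term_cv": float(np.mean(short_cvs))}
    if len(records) >= 2:
        mu = float(np.mean(first_means))
        if mu == 0:
            raise InvalidInputError("zero-mean signals: CV undefined")
        out["long_term_cv"] = float(np.std(first_means) / mu)
    return out
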