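"""Respiratory gate generation.

The respiration channel is digitized every 10 ms.  In the default
(differential) mode a 2-point differential of adjacent samples acts as a
high-pass filter removing baseline drift; a threshold binarisation of that
filtered signal starts a dTTL_Threshold pulse, which terminates when the
filtered signal falls through

    onset_voltage + trailing_fraction * (max_during_pulse - onset_voltage)

(the 20 %-of-excursion rule, guarding against artificially long pulses when
the baseline is not re-reached between breaths).  The pulse extended by a
user dial forms dTTL_NoAcquire; the remainder of the timeline is the
dTTL_Acquire window, terminated early by the next breath and optionally
truncated to a maximum duration.

In slope mode the pulse *starts* when the per-sample slope of the analogue
signal exceeds the threshold and *terminates* when the analogue voltage
returns through 20 % of the excursion between detection and peak.

Crossings are evaluated sample-and-compare on the 10 ms grid, as the
microprocessor does; no sub-sample interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .trace import WaveformTrace
from .ttl import TTLSignal

__all__ = ["RespGateConfig", "RespGateResult",
           "resp_differential", "detect_breaths", "slope_trigger"]

log = logging.getLogger(__name__)

MODE_DIFFERENTIAL = "differential"
MODE_SLOPE = "slope"


@dataclass
class RespGateConfig:
    """Dials of the respiration gating algorithm.

    ``threshold`` applies to the differential signal (volts per sample) in
    differential mode, or to the slope (volts/ms) in slope mode.
    """

    sample_interval: float = 10.0       # ms, respiration digitization grid
    threshold: float = 0.05
    trailing_fraction: float = 0.20
    no_acquire_extension: float = 150.0  # ms past pulse termination
    acquire_max_duration: float | None = None  # manual shortening of dTTL_Acquire
    mode: str = MODE_DIFFERENTIAL
    pulse_timeout: float = 400.0        # force-terminate stuck pulses (ms)

    def __post_init__(self):
        if self.sample_interval <= 0:
            raise InvalidParameterError("sample_interval must be > 0")
        if not (0.0 < self.trailing_fraction < 1.0):
            raise InvalidParameterError("trailing_fraction must lie in (0, 1)")
        if self.no_acquire_extension < 0:
            raise InvalidParameterError("no_acquire_extension must be >= 0")
        if self.acquire_max_duration is not None and self.acquire_max_duration <= 0:
            raise InvalidParameterError("acquire_max_duration must be > 0 when set")
        if self.mode not in (MODE_DIFFERENTIAL, MODE_SLOPE):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if self.pulse_timeout <= 0:
            raise InvalidParameterError("pulse_timeout must be > 0")


@dataclass
class RespGateResult:
    """Gating outputs: threshold pulses, no-acquire and acquire windows."""

    threshold_ttl: TTLSignal
    no_acquire_ttl: TTLSignal
    acquire_ttl: TTLSignal
    filtered_trace: WaveformTrace
    n_forced_terminations: int = 0

    @property
    def n_breaths(self) -> int:
        return int(self.threshold_ttl.starts.size)


def resp_differential(trace: WaveformTrace, cfg: RespGateConfig) -> WaveformTrace:
    """2-point differential on the gating sample grid (first sample = 0).

    Acts as a high-pass filter: a drift of period P contributes at most
    2*pi*A*dt/P volts per sample, so slow baseline wander is suppressed.
    """
    g = _on_grid(trace, cfg)
    if g.values.size < 2:
        raise InvalidInputError("trace must contain at least 2 samples on the gating grid")
    d = np.empty_like(g.values)
    d[0] = 0.0
    d[1:] = np.diff(g.values)
    return g.with_values(d, label=f"{trace.channel_label}_diff")


def detect_breaths(trace: WaveformTrace, cfg: RespGateConfig) -> RespGateResult:
    """Run the differential-mode gate over a voltage-scaled respiration trace."""
    if cfg.mode != MODE_DIFFERENTIAL:
        raise InvalidParameterError("detect_breaths requires differential mode")
    return _run_gate(trace, cfg)


def slope_trigger(trace: WaveformTrace, cfg: RespGateConfig) -> RespGateResult:
    """Run the slope-mode gate: arm on leading-edge slope, terminate on voltage."""
    if cfg.mode != MODE_SLOPE:
        raise InvalidParameterError("slope_trigger requires slope mode")
    return _run_gate(trace, cfg)


def _on_grid(trace: WaveformTrace, cfg: RespGateConfig) -> WaveformTrace:
    if abs(trace.sample_interval - cfg.sample_interval) < 1e-9:
        return trace
    return trace.decimate(cfg.sample_interval)


def _run_gate(trace: WaveformTrace, cfg: RespGateConfig) -> RespGateResult:
    if cfg.threshold <= 0:
        raise InvalidParameterError("threshold must be > 0")
    g = _on_grid(trace, cfg)
    v = g.values
    t = g.times
    if cfg.mode == MODE_DIFFERENTIAL:
        det = resp_differential(trace, cfg).values   # arm and terminate on this
        term = det
        filtered = g.with_values(det, label=f"{trace.channel_label}_diff")
    else:
        slope = np.empty_like(v)
        slope[0] = 0.0
        slope[1:] = np.diff(v) / cfg.sample_interval
        det = slope                                   # arm on slope ...
        term = v                                      # ... terminate on voltage
        filtered = g.with_values(slope, label=f"{trace.channel_label}_slope")

    pulses: list[tuple[float, float]] = []
    n_forced = 0
    in_pulse = False
    onset_v = 0.0
    peak_v = 0.0
    start_t = 0.0
    prev_below = True
    for k in range(v.size):
        if not in_pulse:
            crossed = det[k] >= cfg.threshold and prev_below
            prev_below = det[k] < cfg.threshold
            if crossed:
                in_pulse = True
                start_t = t[k]
                onset_v = term[k]   # first sample at/above threshold defines onset
                peak_v = term[k]
        else:
            peak_v = max(peak_v, term[k])
            level = onset_v + cfg.trailing_fraction * (peak_v - onset_v)
            if term[k] < level:
                pulses.append((start_t, t[k]))
                in_pulse = False
                prev_below = det[k] < cfg.threshold
            elif t[k] - start_t >= cfg.pulse_timeout:
                log.warning("resp gate: pulse at %.1f ms never crossed its "
                            "termination level; force-terminated after %.0f ms",
                            start_t, cfg.pulse_timeout)
                n_forced += 1
                pulses.append((start_t, t[k]))
                in_pulse = False
                prev_below = det[k] < cfg.threshold
    if in_pulse:
        n_forced += 1
        pulses.append((start_t, t[-1]))

    t0, t1 = float(t[0]), float(t[-1])
    threshold_ttl = TTLSignal.from_intervals(pulses, t0, t1, label="dTTL_Threshold")

    # no-acquire = threshold pulse extended by the user dial, merged if touching
    merged: list[list[float]] = []
    for s, e in pulses:
        e_ext = min(e + cfg.no_acquire_extension, t1)
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e_ext)
        else:
            merged.append([s, e_ext])
    no_acq = [(s, e) for s, e in merged if e > s]

    # acquire tiles the remainder; optionally truncated, remainder -> no-acquire
    acquire: list[tuple[float, float]] = []
    extra_no_acq: list[tuple[float, float]] = []
    prev = t0
    bounds = no_acq + [(t1, t1)]
    for s, e in bounds:
        if s > prev:
            a0, a1 = prev, s
            if cfg.acquire_max_duration is not None and (a1 - a0) > cfg.acquire_max_duration:
                cut = a0 + cfg.acquire_max_duration
                acquire.append((a0, cut))
                extra_no_acq.append((cut, a1))
            else:
                acquire.append((a0, a1))
        prev = max(prev, e)

    all_no_acq = sorted(no_acq + extra_no_acq)
    # merge adjacent/overlapping no-acquire segments
    merged2: list[list[float]] = []
    for s, e in all_no_acq:
        if merged2 and s <= merged2[-1][1] + 1e-9:
            merged2[-1][1] = max(merged2[-1][1], e)
        else:
            merged2.append([s, e])
    no_acquire_ttl = TTLSignal.from_intervals(
        [(s, e) for s, e in merged2 if e > s], t0, t1, label="dTTL_NoAcquire")
    acquire_ttl = TTLSignal.from_intervals(acquire, t0, t1, label="dTTL_Acquire")

    return RespGateResult(
        threshold_ttl=threshold_ttl,
        no_acquire_ttl=no_acquire_ttl,
        acquire_ttl=acquire_ttl,
        filtered_trace=filtered,
        n_forced_terminations=n_forced,
    )
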