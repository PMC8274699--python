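"""Seeded synthetic respiration and ECG generators with ground-truth events.

The gating control unit being emulated includes a built-in signal simulator so
scanner commissioning and QC can run without animals: cardiac and respiratory
pulse trains with slightly variable periods (uniform jitter of mean ± span,
defaults 134(±10) ms cardiac and 1000(±100) ms respiratory for the mouse).
Only the periods are prescribed by the device; the waveform shapes here are
modelling choices documented in docs/methods.md:

* R-wave: a narrow positive Gaussian (full width at half maximum
  ``r_wave_width``, true width ~2.5 ms) flanked by smaller opposite-sign
  lobes, riding on a slow respiration-coupled baseline so the downstream
  2-point difference has a drift to remove.
* Breath: a unipolar raised-cosine pulse of ``breath_pulse_width`` on a slow
  sinusoidal baseline drift.

Everything is simulated on a fast master grid (default 10 kHz, the fastest
digitization rate of the gating unit) and decimated downstream for the slower
channels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .trace import WaveformTrace

__all__ = [
    "PhysioParams",
    "EventGroundTruth",
    "simulate_cardiac",
    "simulate_respiration",
    "add_gradient_noise",
    "r_wave_peak_to_peak",
]


@dataclass
class PhysioParams:
    """Dials of the synthetic physiology simulator (ms / volts)."""

    resp_period_mean: float = 1000.0
    resp_period_span: float = 100.0      # half-width of the uniform period jitter
    cardiac_period_mean: float = 134.0
    cardiac_period_span: float = 10.0
    r_wave_width: float = 2.5            # FWHM of the R peak, pre-amplifier
    r_wave_amplitude: float = 1.0
    breath_pulse_width: float = 200.0
    breath_amplitude: float = 6.0
    baseline_drift_amplitude: float = 0.5
    baseline_drift_period: float = 30000.0
    gradient_noise_fraction: float = 0.2  # noise p2p as a fraction of R-wave p2p
    sample_rate: float = 10000.0          # samples per second (master grid)

    def __post_init__(self):
        positive = [
            ("resp_period_mean", self.resp_period_mean),
            ("cardiac_period_mean", self.cardiac_period_mean),
            ("r_wave_width", self.r_wave_width),
            ("r_wave_amplitude", self.r_wave_amplitude),
            ("breath_pulse_width", self.breath_pulse_width),
            ("breath_amplitude", self.breath_amplitude),
            ("baseline_drift_period", self.baseline_drift_period),
            ("sample_rate", self.sample_rate),
        ]
        for name, v in positive:
            if v <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        for name, span, mean in [
            ("resp_period_span", self.resp_period_span, self.resp_period_mean),
            ("cardiac_period_span", self.cardiac_period_span, self.cardiac_period_mean),
        ]:
            if span < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
            if span >= mean:
                raise InvalidParameterError(f"{name} must be smaller than its mean")
        if self.baseline_drift_amplitude < 0:
            raise InvalidParameterError("baseline_drift_amplitude must be >= 0")
        if not (0.0 <= self.gradient_noise_fraction <= 1.0):
            raise InvalidParameterError("gradient_noise_fraction must lie in [0, 1]")
        if self.breath_pulse_width >= self.resp_period_mean - self.resp_period_span:
            raise InvalidParameterError(
                "breath_pulse_width must be shorter than the minimum breath period "
                "(breaths would overlap)"
            )

    @property
    def sample_interval(self) -> float:
        """Master grid spacing in ms."""
        return 1000.0 / self.sample_rate


@dataclass
class EventGroundTruth:
    """True event times (ms) recorded by the simulator."""

    r_peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    breath_onset_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    breath_end_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.r_peak_times = np.asarray(self.r_peak_times, dtype=float)
        self.breath_onset_times = np.asarray(self.breath_onset_times, dtype=float)
        self.breath_end_times = np.asarray(self.breath_end_times, dtype=float)
        for name, arr in [("r_peak_times", self.r_peak_times),
                          ("breath_onset_times", self.breath_onset_times),
                          ("breath_end_times", self.breath_end_times)]:
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise InvalidParameterError(f"{name} must be strictly increasing")
        if self.breath_onset_times.size != self.breath_end_times.size:
            raise InvalidParameterError("breath onset/end lists must pair up")
        if self.breath_onset_times.size and np.any(
            self.breath_end_times <= self.breath_onset_times
        ):
            raise InvalidParameterError("each breath must end after its onset")

    def to_json(self, path=None):
        obj = {
            "r_peak_times_ms": self.r_peak_times.tolist(),
            "breath_onset_times_ms": self.breath_onset_times.tolist(),
            "breath_end_times_ms": self.breath_end_times.tolist(),
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(obj, fh)
        return obj

    @classmethod
    def from_json(cls, source):
        if isinstance(source, dict):
            obj = source
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(
            r_peak_times=obj.get("r_peak_times_ms", []),
            breath_onset_times=obj.get("breath_onset_times_ms", []),
            breath_end_times=obj.get("breath_end_times_ms", []),
        )


def _draw_event_times(rng, mean, span, duration, first, margin):
    """Cumulative event times with uniform period jitter, kept inside duration."""
    times = []
    t = first
    while t <= duration - margin:
        times.append(t)
        t += rng.uniform(mean - span, mean + span) if span > 0 else mean
    return np.array(times)


def _check_sim_args(params, duration, kind):
    mean = params.cardiac_period_mean if kind == "cardiac" else params.resp_period_mean
    if duration <= 0:
        raise InvalidParameterError("duration must be strictly positive")
    if duration <= 3 * mean:
        raise InvalidParameterError(
            f"duration must exceed 3 x {kind} period mean ({3 * mean:g} ms)"
        )


def simulate_cardiac(params: PhysioParams, duration: float, seed: int):
    """Synthetic ECG trace plus ground-truth R-peak times.

    R-R intervals are independent uniform draws from mean ± span.  Each R-wave
    is a positive Gaussian of FWHM ``r_wave_width`` with opposite-sign side
    lobes at ±1.5 widths (15 % amplitude).  A slow sinusoid at the respiratory
    period emulates the respiration-induced voltage the 2-point difference
    filter is meant to reject.  Peak times are snapped to the master grid so
    the trace argmax and the ground truth coincide.
    """
    _check_sim_args(params, duration, "cardiac")
    rng = np.random.default_rng(seed)
    dt = params.sample_interval
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt

    margin = 4 * params.r_wave_width
    peaks = _draw_event_times(
        rng, params.cardiac_period_mean, params.cardiac_period_span,
        duration, first=params.cardiac_period_mean, margin=margin,
    )
    # snap to the sampling grid so argmax == ground truth for clean traces
    peaks = np.round(peaks / dt) * dt

    values = np.zeros(n)
    if params.baseline_drift_amplitude > 0:
        values += params.baseline_drift_amplitude * np.sin(
            2 * np.pi * t / params.resp_period_mean
        )

    sigma = params.r_wave_width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    lobe_offset = 1.5 * params.r_wave_width
    lobe_sigma = 0.8 * params.r_wave_width
    half_window = lobe_offset + 4 * lobe_sigma
    hw = int(round(half_window / dt))
    for tp in peaks:
        ip = int(round(tp / dt))
        lo, hi = max(0, ip - hw), min(n, ip + hw + 1)
        tt = t[lo:hi] - tp
        tpl = params.r_wave_amplitude * (
            np.exp(-0.5 * (tt / sigma) ** 2)
            - 0.15 * np.exp(-0.5 * ((tt - lobe_offset) / lobe_sigma) ** 2)
            - 0.15 * np.exp(-0.5 * ((tt + lobe_offset) / lobe_sigma) ** 2)
        )
        values[lo:hi] += tpl

    trace = WaveformTrace(0.0, dt, values, channel_label="raw_ecg")
    truth = EventGroundTruth(r_peak_times=peaks)
    return trace, truth


def simulate_respiration(params: PhysioParams, duration: float, seed: int):
    """Synthetic respiration trace plus ground-truth breath onset/end times.

    Breaths are unipolar raised-cosine pulses of ``breath_pulse_width`` whose
    onsets repeat with uniform period jitter, on a slow sinusoidal baseline
    drift (amplitude/period dials; zero amplitude gives an exactly flat
    inter-breath baseline).
    """
    _check_sim_args(params, duration, "respiration")
    rng = np.random.default_rng(seed)
    dt = params.sample_interval
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt

    onsets = _draw_event_times(
        rng, params.resp_period_mean, params.resp_period_span,
        duration, first=0.5 * params.resp_period_mean,
        margin=params.breath_pulse_width,
    )
    onsets = np.round(onsets / dt) * dt
    ends = onsets + params.breath_pulse_width

    values = np.zeros(n)
    if params.baseline_drift_amplitude > 0:
        values += params.baseline_drift_amplitude * np.sin(
            2 * np.pi * t / params.baseline_drift_period
        )
    w = params.breath_pulse_width
    nw = int(round(w / dt))
    for onset in onsets:
        i0 = int(round(onset / dt))
        i1 = min(n, i0 + nw + 1)
        tt = t[i0:i1] - onset
        values[i0:i1] += 0.5 * params.breath_amplitude * (1 - np.cos(2 * np.pi * tt / w))

    trace = WaveformTrace(0.0, dt, values, channel_label="raw_resp")
    truth = EventGroundTruth(breath_onset_times=onsets, breath_end_times=ends)
    return trace, truth


def add_gradient_noise(
    trace: WaveformTrace,
    burst_period: float,
    burst_width: float,
    fraction: float,
    reference_p2p: float,
    seed: int,
) -> WaveformTrace:
    """Superimpose per-TR gradient-switching noise bursts on a trace.

    Every ``burst_period`` ms a zero-mean oscillatory burst of ``burst_width``
    ms is added, with peak-to-peak amplitude ``fraction * reference_p2p`` (the
    observed worst case on the real system is ~20 % of the R-wave peak-to-peak
    voltage).  The oscillation runs at a quarter of the sample rate so samples
    land exactly on the extrema; each burst gets a random sign and phase offset
    and is truncated to whole cycles, so the injected component sums to exactly
    zero.  The input trace is left unmodified.
    """
    if fraction < 0:
        raise InvalidParameterError("fraction must be >= 0")
    if not (burst_period > burst_width > 0):
        raise InvalidParameterError("need burst_period > burst_width > 0")
    dt = trace.sample_interval
    period_n = burst_period / dt
    if abs(period_n - round(period_n)) > 1e-6:
        raise InvalidParameterError(
            "burst_period must be an integer multiple of the trace sample interval"
        )
    period_n = int(round(period_n))
    if period_n < 4:
        raise InvalidParameterError("burst_period too short for the trace sample rate")
    out = trace.values.copy()
    if fraction == 0 or reference_p2p == 0:
        return trace.with_values(out)

    rng = np.random.default_rng(seed)
    amp = 0.5 * fraction * reference_p2p
    burst_n = int(round(burst_width / dt))
    burst_n -= burst_n % 4            # whole oscillation cycles -> exact zero sum
    if burst_n < 4:
        raise InvalidParameterError("burst_width too short for the trace sample rate")
    cycle = np.array([0.0, 1.0, 0.0, -1.0])
    n = out.size
    for start in range(0, n, period_n):
        stop = start + burst_n
        if stop > n:
            break
        sign = 1.0 if rng.random() < 0.5 else -1.0
        phase = rng.integers(0, 4)
        pattern = np.roll(cycle, phase)
        out[start:stop] += sign * amp * np.tile(pattern, burst_n // 4)
    return trace.with_values(out)


def r_wave_peak_to_peak(trace: WaveformTrace, truth: EventGroundTruth,
                        window: float = 8.0) -> float:
    """Median per-beat peak-to-peak excursion around the true R-peak times.

    Used as the reference amplitude when scaling gradient noise, mirroring the
    'fraction of the R-wave peak-to-peak voltage' convention.
    """
    if truth.r_peak_times.size == 0:
        raise InvalidInputError("ground truth contains no R peaks")
    p2p = []
    for tp in truth.r_peak_times:
        if tp - window < trace.start_time or tp + window > trace.end_time:
            continue
        lo = trace.index_at(tp - window)
        hi = trace.index_at(tp + window) + 1
        seg = trace.values[lo:hi]
        p2p.append(float(seg.max() - seg.min()))
    if not p2p:
        raise InvalidInputError("no R peaks fall fully inside the trace")
    return float(np.median(p2p))
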