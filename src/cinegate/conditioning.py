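"""Analogue front-end emulation: amplifier delay/broadening and voltage scaling.

Two documented facts pin the amplifier model: the ECG amplifier's audio filters
delay the signal by 4 ms and broaden a ~2.5 ms R-wave to ~7 ms; the
respiration amplifier's 10 Hz low-pass delays by >50 ms.  The exact filter
families are proprietary, so the stand-in is a pure propagation delay plus a
normalized moving average (which reproduces both facts), with an optional
slew-rate clamp.

The scaling board maps the amplifiers' ±10 V range onto the 0–5 V
microprocessor input range with gain and DC-offset dials; out-of-range inputs
saturate (as the hardware does) and saturation events are counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .trace import WaveformTrace

__all__ = ["AmplifierModel", "ScalerConfig", "ScaleResult",
           "apply_amplifier", "scale_voltage"]

log = logging.getLogger(__name__)


@dataclass
class AmplifierModel:
    """Propagation delay + moving-average broadening for one channel."""

    propagation_delay: float = 4.0   # ms
    smoothing_width: float = 4.0     # ms, moving-average window (0 = off)
    channel: str = "ecg"
    slew_rate_limit: float | None = None  # V/ms, optional max |dV/dt| clamp

    def __post_init__(self):
        if self.propagation_delay < 0:
            raise InvalidParameterError("propagation_delay must be >= 0")
        if self.smoothing_width < 0:
            raise InvalidParameterError("smoothing_width must be >= 0")
        if self.channel not in ("ecg", "resp"):
            raise InvalidParameterError("channel must be 'ecg' or 'resp'")

    @classmethod
    def ecg_default(cls) -> "AmplifierModel":
        """4 ms audio-filter delay; window sized to broaden ~2.5 ms to ~7 ms."""
        return cls(propagation_delay=4.0, smoothing_width=4.0, channel="ecg")

    @classmethod
    def resp_default(cls) -> "AmplifierModel":
        """10 Hz low-pass stand-in: >50 ms delay, heavy smoothing."""
        return cls(propagation_delay=52.0, smoothing_width=30.0, channel="resp")


@dataclass
class ScalerConfig:
    """±10 V -> 0–5 V voltage scaling board with gain and DC-offset dials."""

    input_min: float = -10.0
    input_max: float = 10.0
    output_min: float = 0.0
    output_max: float = 5.0
    gain: float = 1.0
    dc_offset: float = 0.0

    def __post_init__(self):
        if self.input_max <= self.input_min:
            raise InvalidParameterError("input_max must exceed input_min")
        if self.output_max <= self.output_min:
            raise InvalidParameterError("output_max must exceed output_min")

    def map(self, v: np.ndarray) -> np.ndarray:
        """Affine map + gain/offset, before clipping."""
        span_in = self.input_max - self.input_min
        span_out = self.output_max - self.output_min
        y = self.output_min + (v - self.input_min) * span_out / span_in
        mid = 0.5 * (self.output_min + self.output_max)
        return mid + self.gain * (y - mid) + self.dc_offset

    def unmap(self, y: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`map` (valid when no clipping occurred)."""
        if self.gain == 0:
            raise InvalidParameterError("cannot invert zero gain")
        mid = 0.5 * (self.output_min + self.output_max)
        y0 = (np.asarray(y, dtype=float) - self.dc_offset - mid) / self.gain + mid
        span_in = self.input_max - self.input_min
        span_out = self.output_max - self.output_min
        return self.input_min + (y0 - self.output_min) * span_in / span_out


class ScaleResult(NamedTuple):
    trace: WaveformTrace
    clip_count: int


def apply_amplifier(trace: WaveformTrace, model: AmplifierModel) -> WaveformTrace:
    """Delay the trace and broaden it with a normalized moving average.

    The delay is rounded to the sample grid; the leading edge is padded with
    the first sample value (DC hold) and the moving average uses edge padding,
    so the DC level is preserved and the operation is linear in the input.
    """
    dt = trace.sample_interval
    if model.smoothing_width >= trace.duration:
        raise InvalidInputError("smoothing_width must be shorter than the trace")
    v = trace.values
    shift = int(round(model.propagation_delay / dt))
    if shift > 0:
        v = np.concatenate([np.full(shift, v[0]), v[:-shift]]) if shift < v.size else np.full_like(v, v[0])
    m = int(round(model.smoothing_width / dt))
    if m >= 2:
        pad_l = (m - 1) // 2
        pad_r = m - 1 - pad_l
        vp = np.pad(v, (pad_l, pad_r), mode="edge")
        kernel = np.full(m, 1.0 / m)
        v = np.convolve(vp, kernel, mode="valid")
    if model.slew_rate_limit is not None:
        max_step = model.slew_rate_limit * dt
        out = v.copy()
        for k in range(1, out.size):
            step = out[k] - out[k - 1]
            if step > max_step:
                out[k] = out[k - 1] + max_step
            elif step < -max_step:
                out[k] = out[k - 1] - max_step
        v = out
    return trace.with_values(v, label=f"{trace.channel_label}_amp")


def scale_voltage(trace: WaveformTrace, cfg: ScalerConfig) -> ScaleResult:
    """Scale a trace through the voltage board; saturating samples are counted.

    Returns the scaled trace together with the number of clipped samples
    (hardware saturates rather than fails; clipping is logged as a warning).
    """
    y = cfg.map(trace.values)
    clipped = (y < cfg.output_min) | (y > cfg.output_max)
    n_clip = int(np.count_nonzero(clipped))
    if n_clip:
        log.warning("scale_voltage: %d samples clipped to [%g, %g] V on %s",
                    n_clip, cfg.output_min, cfg.output_max, trace.channel_label)
    y = np.clip(y, cfg.output_min, cfg.output_max)
    return ScaleResult(trace.with_values(y, label=f"{trace.channel_label}_scaled"), n_clip)
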