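"""Uniformly sampled voltage traces.

All times are in milliseconds and all amplitudes in volts, mirroring the
physiological-monitoring chain the package emulates: analogue respiration and
ECG voltages, their conditioned versions, and TTL lines rendered as 0/5 V.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError

__all__ = ["WaveformTrace"]


@dataclass
class WaveformTrace:
    """A voltage-vs-time signal sampled on a uniform grid.

    Sample ``k`` (0-based) sits at ``start_time + k * sample_interval`` ms.
    """

    start_time: float
    sample_interval: float
    values: np.ndarray
    channel_label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_interval <= 0:
            raise InvalidParameterError("sample_interval must be > 0")
        if self.values.ndim != 1 or self.values.size == 0:
            raise InvalidParameterError("values must be a non-empty 1-D array")

    # ------------------------------------------------------------------ basics
    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return self.start_time + np.arange(self.values.size) * self.sample_interval

    @property
    def end_time(self) -> float:
        """Time of the last sample."""
        return self.start_time + (self.values.size - 1) * self.sample_interval

    @property
    def duration(self) -> float:
        """Span from first to last sample in ms."""
        return (self.values.size - 1) * self.sample_interval

    def with_values(self, values: np.ndarray, label: str | None = None) -> "WaveformTrace":
        """Copy of this trace carrying new sample values on the same grid."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            channel_label=self.channel_label if label is None else label,
        )

    # -------------------------------------------------------------- resampling
    def decimate(self, target_interval: float) -> "WaveformTrace":
        """Down-sample to a coarser grid by taking every n-th sample.

        The target interval must be an integer multiple of the native one —
        this emulates a slower digitizer reading the same analogue line, so no
        interpolation or anti-alias filtering is applied.
        """
        ratio = target_interval / self.sample_interval
        n = int(round(ratio))
        if n < 1 or abs(ratio - n) > 1e-9:
            raise InvalidParameterError(
                f"target interval {target_interval} ms is not an integer multiple "
                f"of the native interval {self.sample_interval} ms"
            )
        if n == 1:
            return replace(self, values=self.values.copy())
        return replace(
            self,
            sample_interval=self.sample_interval * n,
            values=self.values[::n].copy(),
        )

    def index_at(self, time_ms: float) -> int:
        """Index of the sample at/just before ``time_ms``."""
        idx = int(np.floor((time_ms - self.start_time) / self.sample_interval + 1e-9))
        if idx < 0 or idx >= self.values.size:
            raise InvalidInputError(f"time {time_ms} ms outside trace")
        return idx

    # --------------------------------------------------------------------- I/O
    def to_csv(self, path) -> None:
        """Write as two-column CSV (``time_ms,volts``) at full float precision."""
        df = pd.DataFrame({"time_ms": self.times, "volts": self.values})
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, channel_label: str = "") -> "WaveformTrace":
        df = pd.read_csv(path, float_precision="round_trip")
        if not {"time_ms", "volts"}.issubset(df.columns):
            raise InvalidInputError("trace CSV must have columns time_ms,volts")
        t = df["time_ms"].to_numpy(dtype=float)
        if t.size < 2:
            raise InvalidInputError("trace CSV must contain at least 2 samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=0, atol=1e-6 * max(dt[0], 1.0)):
            raise InvalidInputError("trace CSV is not uniformly sampled")
        return cls(
            start_time=float(t[0]),
            sample_interval=float(dt[0]),
            values=df["volts"].to_numpy(dtype=float),
            channel_label=channel_label,
        )
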