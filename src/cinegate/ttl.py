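"""Binary (TTL) control lines represented as ordered high intervals.

The scanner-facing outputs of the gating unit are 0/5 V logic lines.  They are
stored as sorted, non-overlapping ``[start, end)`` intervals in ms together
with a polarity flag: some scanners treat 5 V as the instruction to image,
others 0 V, so the sense of the line is switchable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .trace import WaveformTrace

__all__ = ["TTLSignal", "HIGH_MEANS_ACQUIRE", "LOW_MEANS_ACQUIRE"]

HIGH_MEANS_ACQUIRE = "high_means_acquire"
LOW_MEANS_ACQUIRE = "low_means_acquire"


@dataclass
class TTLSignal:
    """A logic line as ordered high intervals over ``[t0, t1)``.

    ``starts``/``ends`` are parallel arrays of interval edges (ms); ``t0``/``t1``
    bound the monitored window so that the complement is well defined.
    """

    starts: np.ndarray
    ends: np.ndarray
    t0: float
    t1: float
    polarity: str = HIGH_MEANS_ACQUIRE
    label: str = ""

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        if self.starts.shape != self.ends.shape:
            raise InvalidParameterError("starts and ends must have equal length")
        if self.polarity not in (HIGH_MEANS_ACQUIRE, LOW_MEANS_ACQUIRE):
            raise InvalidParameterError(f"unknown polarity {self.polarity!r}")
        if self.t1 <= self.t0:
            raise InvalidParameterError("t1 must exceed t0")
        if self.starts.size:
            if np.any(self.ends <= self.starts):
                raise InvalidParameterError("each interval must satisfy end > start")
            if np.any(self.starts[1:] < self.ends[:-1]):
                raise InvalidParameterError("intervals must be non-overlapping and sorted")
            if self.starts[0] < self.t0 - 1e-9 or self.ends[-1] > self.t1 + 1e-9:
                raise InvalidParameterError("intervals must lie within [t0, t1]")

    # ------------------------------------------------------------ construction
    @classmethod
    def from_intervals(cls, intervals, t0, t1, polarity=HIGH_MEANS_ACQUIRE, label=""):
        ivs = sorted((float(s), float(e)) for s, e in intervals)
        starts = np.array([s for s, _ in ivs], dtype=float)
        ends = np.array([e for _, e in ivs], dtype=float)
        return cls(starts=starts, ends=ends, t0=float(t0), t1=float(t1),
                   polarity=polarity, label=label)

    @property
    def intervals(self) -> list[tuple[float, float]]:
        return list(zip(self.starts.tolist(), self.ends.tolist()))

    @property
    def onsets(self) -> np.ndarray:
        """Rising-edge times of the high intervals."""
        return self.starts.copy()

    # ----------------------------------------------------------------- queries
    def level_at(self, times) -> np.ndarray:
        """Boolean high/low level at the given time(s); high on [start, end)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        if self.starts.size == 0:
            out = np.zeros(t.shape, dtype=bool)
        else:
            idx = np.searchsorted(self.starts, t, side="right") - 1
            out = (idx >= 0) & (t < self.ends[np.clip(idx, 0, None)])
        return out if np.ndim(times) else bool(out[0])

    def acquire_level_at(self, times):
        """Whether the line instructs *acquire* at the given time(s)."""
        lvl = self.level_at(times)
        return lvl if self.polarity == HIGH_MEANS_ACQUIRE else ~np.atleast_1d(lvl) if np.ndim(times) else not lvl

    # -------------------------------------------------------------- operations
    def normalized(self) -> "TTLSignal":
        """Equivalent signal in high_means_acquire polarity."""
        if self.polarity == HIGH_MEANS_ACQUIRE:
            return self
        return self.complement()._replace_polarity(HIGH_MEANS_ACQUIRE)

    def _replace_polarity(self, polarity):
        return replace(self, polarity=polarity)

    def flipped_polarity(self) -> "TTLSignal":
        """Same physical intervals, opposite interpretation (the polarity switch)."""
        other = LOW_MEANS_ACQUIRE if self.polarity == HIGH_MEANS_ACQUIRE else HIGH_MEANS_ACQUIRE
        return replace(self, polarity=other)

    def complement(self) -> "TTLSignal":
        """Signal that is high exactly where this one is low, within [t0, t1)."""
        segs = []
        prev = self.t0
        for s, e in self.intervals:
            if s > prev:
                segs.append((prev, s))
            prev = max(prev, e)
        if prev < self.t1:
            segs.append((prev, self.t1))
        return TTLSignal.from_intervals(segs, self.t0, self.t1,
                                        polarity=self.polarity,
                                        label=f"not({self.label})")

    def logical_and(self, other: "TTLSignal", label: str = "") -> "TTLSignal":
        """Boolean AND of two lines (both must be high_means_acquire)."""
        if self.polarity != HIGH_MEANS_ACQUIRE or other.polarity != HIGH_MEANS_ACQUIRE:
            raise InvalidInputError(
                "logical_and requires both signals in high_means_acquire polarity; "
                "call normalized() first"
            )
        t0 = max(self.t0, other.t0)
        t1 = min(self.t1, other.t1)
        segs = []
        i = j = 0
        a, b = self.intervals, other.intervals
        while i < len(a) and j < len(b):
            s = max(a[i][0], b[j][0])
            e = min(a[i][1], b[j][1])
            if e > s:
                segs.append((max(s, t0), min(e, t1)))
            if a[i][1] <= b[j][1]:
                i += 1
            else:
                j += 1
        segs = [(s, e) for s, e in segs if e > s]
        return TTLSignal.from_intervals(segs, t0, t1, label=label)

    def total_high_time(self) -> float:
        return float(np.sum(self.ends - self.starts)) if self.starts.size else 0.0

    # --------------------------------------------------------------------- I/O
    def to_json(self, path=None):
        """Export as JSON: list of {start_ms, end_ms, label} plus window/polarity."""
        obj = {
            "t0_ms": self.t0,
            "t1_ms": self.t1,
            "polarity": self.polarity,
            "label": self.label,
            "intervals": [
                {"start_ms": s, "end_ms": e, "label": self.label}
                for s, e in self.intervals
            ],
        }
        if path is None:
            return obj
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)
        return obj

    @classmethod
    def from_json(cls, source) -> "TTLSignal":
        if isinstance(source, dict):
            obj = source
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls.from_intervals(
            [(iv["start_ms"], iv["end_ms"]) for iv in obj["intervals"]],
            obj["t0_ms"], obj["t1_ms"], polarity=obj["polarity"], label=obj.get("label", ""),
        )

    def render(self, sample_interval: float, high_volts: float = 5.0) -> WaveformTrace:
        """Sampled 0/5 V rendering for plotting alongside analogue traces."""
        n = max(2, int(np.floor((self.t1 - self.t0) / sample_interval)) + 1)
        t = self.t0 + np.arange(n) * sample_interval
        v = np.where(self.level_at(t), high_volts, 0.0)
        return WaveformTrace(start_time=self.t0, sample_interval=sample_interval,
                             values=v, channel_label=self.label)
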