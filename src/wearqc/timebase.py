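"""Core time-series and interval data model for wrist-wearable recordings.

All timestamps are UTC epoch seconds (floats).  Fixed-rate channels are
``UniformSeries``; event-like channels (inter-beat intervals) are
``IrregularSeries``; a participant session is a ``Recording``; sets of
half-open time intervals (wear sessions, non-wear bouts, analysis windows)
are ``IntervalSet``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UniformSeries",
    "IrregularSeries",
    "SQISeries",
    "Recording",
    "IntervalSet",
    "ValidationError",
    "E4_RATES",
]

#: Native Empatica-E4 sample rates per channel (Hz).
E4_RATES = {"ACC": 32.0, "EDA": 4.0, "TEMP": 4.0, "BVP": 64.0}


class ValidationError(ValueError):
    """An input violates a data-model invariant."""


@dataclass
class UniformSeries:
    """Fixed-rate samples with a start time.

    Sample ``i`` is located at ``start_time + i / sample_rate_hz``.  Values
    are a float array of shape ``(n,)`` for scalar channels or ``(n, k)``
    for vector channels (``k = 3`` for the accelerometer).

    Parameters
    ----------
    channel_name : str
        Channel label, e.g. ``"EDA"``.
    start_time : float
        UTC epoch seconds of the first sample.
    sample_rate_hz : float
        Sampling rate; must be positive.
    values : ndarray
        Finite sample values.
    units : str
        Physical units (``g``, ``μS``, ``°C``, ``a.u.``).
    """

    channel_name: str
    start_time: float
    sample_rate_hz: float
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (1, 2):
            raise ValidationError(
                f"{self.channel_name}: values must be 1-D or 2-D, "
                f"got ndim={self.values.ndim}"
            )
        if not np.isfinite(self.sample_rate_hz) or self.sample_rate_hz <= 0:
            raise ValidationError(
                f"{self.channel_name}: sample_rate_hz must be positive, "
                f"got {self.sample_rate_hz}"
            )
        if not np.isfinite(self.start_time):
            raise ValidationError(f"{self.channel_name}: non-finite start_time")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.channel_name}: non-finite sample values")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    @property
    def duration_s(self) -> float:
        """Span covered by the samples, each owning one sampling period."""
        return len(self) / self.sample_rate_hz

    def timestamps(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) / self.sample_rate_hz

    def replace_values(self, values: np.ndarray, units: str | None = None) -> "UniformSeries":
        return UniformSeries(
            channel_name=self.channel_name,
            start_time=self.start_time,
            sample_rate_hz=self.sample_rate_hz,
            values=values,
            units=self.units if units is None else units,
        )


@dataclass
class SQISeries:
    """Boolean signal-quality index aligned to a fixed rate.

    ``True`` means on-body / valid.  Shares the timestamp convention of
    :class:`UniformSeries`.
    """

    channel_name: str
    start_time: float
    sample_rate_hz: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 1:
            raise ValidationError("SQI values must be 1-D boolean")
        if self.sample_rate_hz <= 0:
            raise ValidationError("SQI sample_rate_hz must be positive")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz

    def timestamps(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) / self.sample_rate_hz


@dataclass
class IrregularSeries:
    """Timestamped (time, value) pairs at no fixed rate (e.g. IBI).

    Carried opaquely: parsed and written but not consumed by any detector.
    """

    channel_name: str
    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape or self.timestamps.ndim != 1:
            raise ValidationError(
                f"{self.channel_name}: timestamps and values must be equal-length 1-D"
            )
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError(
                f"{self.channel_name}: timestamps must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class Recording:
    """A participant session: named channels plus marker tags."""

    participant_id: str = ""
    session_id: str = ""
    channels: dict = field(default_factory=dict)
    tags: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.tags = np.asarray(self.tags, dtype=float)

    def require(self, name: str) -> UniformSeries:
        """Return a channel or raise a validation error naming it."""
        if name not in self.channels:
            raise ValidationError(f"recording has no {name!r} channel")
        return self.channels[name]


@dataclass
class IntervalSet:
    """Sorted, pairwise-disjoint half-open intervals ``[start, end)``.

    The half-open convention means adjacent intervals sharing a boundary
    do not double-count that instant.
    """

    label: str = ""
    intervals: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if iv.size:
            if np.any(iv[:, 1] <= iv[:, 0]):
                raise ValidationError(f"{self.label}: interval with end <= start")
            order = np.argsort(iv[:, 0], kind="stable")
            iv = iv[order]
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValidationError(f"{self.label}: overlapping intervals")
        self.intervals = iv

    def __len__(self) -> int:
        return self.intervals.shape[0]

    def __iter__(self):
        return iter(map(tuple, self.intervals))

    @property
    def total_duration(self) -> float:
        if not len(self):
            return 0.0
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean membership of each time in the union of intervals."""
        times = np.asarray(times, dtype=float)
        out = np.zeros(times.shape, dtype=bool)
        for s, e in self.intervals:
            out |= (times >= s) & (times < e)
        return out

    def intersect_length(self, start: float, end: float) -> float:
        """Total overlap length with the window ``[start, end)``."""
        if not len(self):
            return 0.0
        lo = np.maximum(self.intervals[:, 0], start)
        hi = np.minimum(self.intervals[:, 1], end)
        return float(np.sum(np.clip(hi - lo, 0.0, None)))

    def clip(self, start: float, end: float) -> "IntervalSet":
        """Intervals restricted to the window ``[start, end)``."""
        if not len(self):
            return IntervalSet(self.label)
        lo = np.maximum(self.intervals[:, 0], start)
        hi = np.minimum(self.intervals[:, 1], end)
        keep = hi > lo
        return IntervalSet(self.label, np.column_stack([lo[keep], hi[keep]]))

    def shift(self, offset: float) -> "IntervalSet":
        return IntervalSet(self.label, self.intervals + offset)
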