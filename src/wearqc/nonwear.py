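"""Multi-modal non-wear detection for wrist wearables.

Two detector variants are implemented, both combining movement (ACC), skin
temperature and skin conductance signal-quality indices (SQIs):

* ``boettcher`` — the algorithm of Böttcher et al.: per-signal thresholds
  (sum of three per-axis 10-s ACC SDs ≥ 0.2 g; 25 °C ≤ T ≤ 40 °C;
  EDA ≥ 0.05 μS), each SQI aggregated per 1-minute window by a ≥ 1 %
  on-body fraction, then OR-combined.  Output granularity: 1 minute.
* ``refined`` — a faster, more sensitive variant: x-axis-only 1-s ACC SD
  ≥ 0.1 g, T ≥ 32 °C, EDA ≥ 0.03 μS; the three SQIs are reindexed to the
  4-Hz EDA timestamps, OR-combined, and majority-smoothed over a 1-minute
  window.  Output granularity: 0.25 s.

All threshold comparisons are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from . import _rolling
from .timebase import IntervalSet, Recording, SQISeries, UniformSeries, ValidationError

__all__ = [
    "RefinedParams",
    "BoettcherParams",
    "rolling_sd",
    "channel_sqi",
    "combine_refined",
    "combine_boettcher",
    "sqi_to_intervals",
    "detect_nonwear",
    "NonwearDetector",
]


@dataclass
class RefinedParams:
    """Thresholds of the refined detector (movement SQI on the ACC x-axis)."""

    acc_sd_window_s: float = 1.0
    acc_sd_threshold_g: float = 0.1
    temp_threshold_c: float = 32.0
    eda_threshold_us: float = 0.03
    smooth_window_s: float = 60.0

    def __post_init__(self) -> None:
        for name in ("acc_sd_window_s", "acc_sd_threshold_g", "temp_threshold_c",
                     "eda_threshold_us", "smooth_window_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class BoettcherParams:
    """Thresholds of Böttcher et al.'s detector (sum of 3-axis ACC SDs)."""

    acc_sd_window_s: float = 10.0
    acc_sd_sum_threshold_g: float = 0.2
    temp_valid_range_c: tuple = (25.0, 40.0)
    eda_threshold_us: float = 0.05
    window_s: float = 60.0
    onbody_fraction: float = 0.01

    def __post_init__(self) -> None:
        lo, hi = self.temp_valid_range_c
        if not lo < hi:
            raise ValidationError("temp_valid_range_c must have lower < upper")
        if not 0.0 < self.onbody_fraction <= 1.0:
            raise ValidationError("onbody_fraction must be in (0, 1]")
        if self.window_s <= 0 or self.acc_sd_window_s <= 0:
            raise ValidationError("window lengths must be positive")


def _window_samples(series, window_s: float) -> int:
    w = int(round(window_s * series.sample_rate_hz))
    if w < 2:
        raise ValidationError(
            f"window of {window_s} s spans fewer than 2 samples at "
            f"{series.sample_rate_hz} Hz"
        )
    return w


def rolling_sd(series: UniformSeries, window_s: float) -> UniformSeries:
    """Centered rolling sample standard deviation, per component.

    One output per input sample; edge windows shrink to the available
    samples (single-sample windows yield 0).
    """
    w = _window_samples(series, window_s)
    return series.replace_values(_rolling.rolling_sd(series.values, w))


def channel_sqi(
    series: UniformSeries,
    channel: str,
    variant: str = "refined",
    params: RefinedParams | BoettcherParams | None = None,
) -> SQISeries:
    """Per-signal boolean SQI at the input rate (True = on-body/valid)."""
    if variant not in ("refined", "boettcher"):
        raise ValidationError(f"unknown variant {variant!r}")
    if params is None:
        params = RefinedParams() if variant == "refined" else BoettcherParams()
    if channel == "ACC":
        if series.n_components != 3:
            raise ValidationError("ACC SQI needs a 3-component series")
        sd = rolling_sd(series, params.acc_sd_window_s).values
        if variant == "refined":
            mask = sd[:, 0] >= params.acc_sd_threshold_g
        else:
            mask = sd.sum(axis=1) >= params.acc_sd_sum_threshold_g
    elif channel == "TEMP":
        v = series.values
        if variant == "refined":
            mask = v >= params.temp_threshold_c
        else:
            lo, hi = params.temp_valid_range_c
            mask = (v >= lo) & (v <= hi)
    elif channel == "EDA":
        mask = series.values >= params.eda_threshold_us
    else:
        raise ValidationError(f"unknown channel {channel!r}")
    return SQISeries(f"{channel}_SQI", series.start_time,
                     series.sample_rate_hz, mask)


def _reindex_to(sqi: SQISeries, start: float, rate: float, n: int) -> np.ndarray:
    """Nearest-sample reindexing onto a uniform target grid.

    A target timestamp picks the nearest source sample if it lies within one
    source sampling period; otherwise it is False (absence of evidence is
    not on-body).
    """
    t = start + np.arange(n) / rate
    period = 1.0 / sqi.sample_rate_hz
    idx = np.round((t - sqi.start_time) * sqi.sample_rate_hz).astype(int)
    ok = (idx >= 0) & (idx < len(sqi))
    out = np.zeros(n, dtype=bool)
    src_t = sqi.start_time + idx[ok] / sqi.sample_rate_hz
    near = np.abs(t[ok] - src_t) <= period
    sel = np.zeros(n, dtype=bool)
    sel[np.flatnonzero(ok)[near]] = True
    out[sel] = sqi.values[idx[sel]]
    return out


def combine_refined(
    acc_sqi: SQISeries,
    temp_sqi: SQISeries,
    eda_sqi: SQISeries,
    params: RefinedParams | None = None,
) -> SQISeries:
    """OR-combine the three SQIs on the EDA timestamps, then majority-smooth.

    The ACC and TEMP SQIs are reindexed (nearest sample) onto the EDA SQI
    grid, combined by OR, and smoothed with a centered 1-minute rolling
    mean thresholded at ≥ 0.5 (ties count as on-body).
    """
    params = params or RefinedParams()
    starts = [acc_sqi.start_time, temp_sqi.start_time, eda_sqi.start_time]
    ends = [s.start_time + s.duration_s for s in (acc_sqi, temp_sqi, eda_sqi)]
    if max(starts) >= min(ends):
        raise ValidationError("SQIs do not overlap in time")
    n = len(eda_sqi)
    combined = (
        eda_sqi.values
        | _reindex_to(acc_sqi, eda_sqi.start_time, eda_sqi.sample_rate_hz, n)
        | _reindex_to(temp_sqi, eda_sqi.start_time, eda_sqi.sample_rate_hz, n)
    )
    w = max(int(round(params.smooth_window_s * eda_sqi.sample_rate_hz)), 1)
    smoothed = _rolling.rolling_mean(combined.astype(float), w) >= 0.5
    return SQISeries("Wrist_SQI", eda_sqi.start_time,
                     eda_sqi.sample_rate_hz, smoothed)


def combine_boettcher(
    acc_sqi: SQISeries,
    temp_sqi: SQISeries,
    eda_sqi: SQISeries,
    params: BoettcherParams | None = None,
) -> SQISeries:
    """Per-minute aggregation then OR.

    Each SQI is reduced per non-overlapping 1-minute window (aligned to the
    earliest SQI start) to True when its within-window on-body fraction is
    at least ``onbody_fraction``; the three window series are OR-combined.
    A trailing partial window is kept.
    """
    params = params or BoettcherParams()
    sqis = (acc_sqi, temp_sqi, eda_sqi)
    if any(len(s) == 0 for s in sqis):
        raise ValidationError("empty SQI input")
    t0 = min(s.start_time for s in sqis)
    t_end = max(s.start_time + s.duration_s for s in sqis)
    n_win = max(int(np.ceil((t_end - t0) / params.window_s)), 1)
    combined = np.zeros(n_win, dtype=bool)
    for s in sqis:
        k = ((s.timestamps() - t0) // params.window_s).astype(int)
        k = np.clip(k, 0, n_win - 1)
        count = np.bincount(k, minlength=n_win)
        true_count = np.bincount(k, weights=s.values.astype(float),
                                 minlength=n_win)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(count > 0, true_count / np.maximum(count, 1), 0.0)
        combined |= frac >= params.onbody_fraction
    return SQISeries("Wrist_SQI", t0, 1.0 / params.window_s, combined)


def sqi_to_intervals(sqi: SQISeries, state: str = "nonwear") -> IntervalSet:
    """Maximal runs of the requested state as half-open epoch intervals.

    Each sample contributes one sampling period, so the on-body and
    non-wear interval sets tile the series span exactly.
    """
    if state not in ("onbody", "nonwear"):
        raise ValidationError(f"unknown state {state!r}")
    if len(sqi) == 0:
        raise ValidationError("empty SQI")
    want = sqi.values if state == "onbody" else ~sqi.values
    period = 1.0 / sqi.sample_rate_hz
    padded = np.concatenate([[False], want, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts = edges[0::2]
    ends = edges[1::2]
    iv = np.column_stack([sqi.start_time + starts * period,
                          sqi.start_time + ends * period])
    return IntervalSet(state, iv)


class NonwearDetector(BaseEstimator):
    """Non-wear detector over an E4-style :class:`Recording`.

    Parameters
    ----------
    variant : {"refined", "boettcher"}
        Algorithm variant; see the module docstring.
    params : RefinedParams or BoettcherParams, optional
        Threshold overrides; defaults are the variant's published values.

    Attributes
    ----------
    wrist_sqi_ : SQISeries
        Combined on-body SQI from the last :meth:`detect` call.
    nonwear_ : IntervalSet
        Detected non-wear bouts from the last :meth:`detect` call.
    """

    def __init__(self, variant: str = "refined", params=None):
        self.variant = variant
        self.params = params

    def _resolved_params(self):
        if self.params is not None:
            return self.params
        return RefinedParams() if self.variant == "refined" else BoettcherParams()

    def fit(self, rec: Recording | None = None, y=None) -> "NonwearDetector":
        """Validate parameters; the detector is threshold-based (stateless)."""
        if self.variant not in ("refined", "boettcher"):
            raise ValidationError(f"unknown variant {self.variant!r}")
        self.params_ = self._resolved_params()
        return self

    def detect(self, rec: Recording) -> tuple[SQISeries, IntervalSet]:
        """Run the full pipeline: per-channel SQIs → combination → intervals."""
        self.fit(rec)
        p = self.params_
        acc = rec.require("ACC")
        temp = rec.require("TEMP")
        eda = rec.require("EDA")
        acc_sqi = channel_sqi(acc, "ACC", self.variant, p)
        temp_sqi = channel_sqi(temp, "TEMP", self.variant, p)
        eda_sqi = channel_sqi(eda, "EDA", self.variant, p)
        if self.variant == "refined":
            wrist = combine_refined(acc_sqi, temp_sqi, eda_sqi, p)
        else:
            wrist = combine_boettcher(acc_sqi, temp_sqi, eda_sqi, p)
        self.wrist_sqi_ = wrist
        self.nonwear_ = sqi_to_intervals(wrist, "nonwear")
        return wrist, self.nonwear_

    def predict(self, rec: Recording) -> np.ndarray:
        """Boolean on-body prediction on the combined SQI grid."""
        wrist, _ = self.detect(rec)
        return wrist.values


def detect_nonwear(
    rec: Recording,
    variant: str = "refined",
    params=None,
) -> tuple[SQISeries, IntervalSet]:
    """Functional wrapper over :class:`NonwearDetector`."""
    return NonwearDetector(variant=variant, params=params).detect(rec)
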