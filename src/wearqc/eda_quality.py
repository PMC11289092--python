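"""Electrodermal-activity artifact processing.

A composite validity SQI marks each EDA sample as usable: the sample must be
physiologically plausible, its local noise amplitude must stay under a
threshold, and the wrist must be on-body.  Brief invalid runs are linearly
interpolated; longer ones are discarded, and any surviving segment shorter
than one minute is excluded as analytically useless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from ._rolling import rolling_mean
from .nonwear import _reindex_to
from .timebase import IntervalSet, SQISeries, UniformSeries, ValidationError

__all__ = [
    "EdaQualityParams",
    "ProcessedSignal",
    "noise_amplitude",
    "eda_validity_sqi",
    "process_signal",
    "EdaQualityProcessor",
]


@dataclass
class EdaQualityParams:
    """Tunables of the EDA validity/processing pipeline.

    ``noise_threshold_us`` and ``max_interp_gap_s`` are deliberate,
    configurable choices (0.1 μS and 5 s by default); the 60-s minimum
    segment length and the 2-s noise-averaging window are fixed pipeline
    constants.
    """

    noise_window_s: float = 2.0
    noise_threshold_us: float = 0.1
    smooth_baseline_window_s: float = 1.0
    max_interp_gap_s: float = 5.0
    min_segment_s: float = 60.0
    plausible_range_us: tuple = (0.01, 100.0)

    def __post_init__(self) -> None:
        for name in ("noise_window_s", "noise_threshold_us",
                     "smooth_baseline_window_s", "max_interp_gap_s",
                     "min_segment_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.min_segment_s <= self.max_interp_gap_s:
            raise ValidationError("min_segment_s must exceed max_interp_gap_s")


@dataclass
class ProcessedSignal:
    """Output of :func:`process_signal`.

    ``values`` holds the processed samples on the source grid (NaN where
    dropped); ``retained`` and ``interpolated`` are per-sample masks, and
    ``segments`` the half-open intervals of retained data.  Retained
    non-interpolated samples equal their source values exactly.
    """

    source: UniformSeries
    validity: SQISeries
    values: np.ndarray
    retained: np.ndarray
    interpolated: np.ndarray
    segments: IntervalSet


def noise_amplitude(eda: UniformSeries, params: EdaQualityParams | None = None) -> UniformSeries:
    """Local noise amplitude: 2-s mean of |residual about a 1-s baseline|.

    The residual is the sample minus a centered rolling mean over
    ``smooth_baseline_window_s``; its absolute value is then averaged over
    ``noise_window_s``.  Output is non-negative, at the input rate.
    """
    params = params or EdaQualityParams()
    rate = eda.sample_rate_hz
    if rate < 4.0:
        raise ValidationError("EDA noise estimation requires >= 4 Hz input")
    w_noise = int(round(params.noise_window_s * rate))
    if len(eda) < w_noise:
        raise ValidationError("series shorter than the noise window")
    # odd (symmetric) baseline window so linear trends cancel in the residual
    w_base = max(int(round(params.smooth_baseline_window_s * rate)), 1)
    w_base += 1 - w_base % 2
    resid = eda.values - rolling_mean(eda.values, w_base)
    out = rolling_mean(np.abs(resid), w_noise)
    return eda.replace_values(out)


def eda_validity_sqi(
    eda: UniformSeries,
    wrist_sqi: SQISeries,
    params: EdaQualityParams | None = None,
) -> SQISeries:
    """Composite per-sample validity: low noise AND plausible AND on-body."""
    params = params or EdaQualityParams()
    end_eda = eda.start_time + eda.duration_s
    end_sqi = wrist_sqi.start_time + wrist_sqi.duration_s
    if max(eda.start_time, wrist_sqi.start_time) >= min(end_eda, end_sqi):
        raise ValidationError("EDA and wrist SQI do not overlap in time")
    noise = noise_amplitude(eda, params).values
    lo, hi = params.plausible_range_us
    plausible = (eda.values >= lo) & (eda.values <= hi)
    onbody = _reindex_to(wrist_sqi, eda.start_time, eda.sample_rate_hz, len(eda))
    valid = (noise < params.noise_threshold_us) & plausible & onbody
    return SQISeries("EDA_validity", eda.start_time, eda.sample_rate_hz, valid)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [i0, i1) index runs where mask is True."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[0::2], edges[1::2]))


def process_signal(
    eda: UniformSeries,
    sqi: SQISeries,
    params: EdaQualityParams | None = None,
) -> ProcessedSignal:
    """Interpolate brief invalid runs, drop long ones and short segments.

    Invalid runs no longer than ``max_interp_gap_s`` with valid data on both
    sides are filled by linear interpolation between the flanking samples
    and retained (flagged as interpolated); longer runs — and leading or
    trailing runs, which have no flank to interpolate from — are dropped.
    Contiguous retained segments shorter than ``min_segment_s`` (a segment
    of exactly that length is kept) are then excluded.
    """
    params = params or EdaQualityParams()
    if abs(sqi.sample_rate_hz - eda.sample_rate_hz) > 1e-9:
        raise ValidationError("SQI rate must equal the EDA rate")
    if len(sqi) != len(eda):
        raise ValidationError("SQI and EDA must have the same length")
    rate = eda.sample_rate_hz
    valid = sqi.values.copy()
    values = np.where(valid, eda.values, np.nan)
    interpolated = np.zeros(len(eda), dtype=bool)
    retained = valid.copy()
    for i0, i1 in _runs(~valid):
        run_s = (i1 - i0) / rate
        has_flanks = i0 > 0 and i1 < len(eda)
        if run_s <= params.max_interp_gap_s and has_flanks:
            x = np.arange(i0, i1)
            values[i0:i1] = np.interp(
                x, [i0 - 1, i1], [eda.values[i0 - 1], eda.values[i1]]
            )
            interpolated[i0:i1] = True
            retained[i0:i1] = True
    # segment floor: drop contiguous retained stretches shorter than the minimum
    min_samples = int(round(params.min_segment_s * rate))
    seg_bounds = []
    for i0, i1 in _runs(retained):
        if i1 - i0 >= min_samples:
            seg_bounds.append((i0, i1))
        else:
            retained[i0:i1] = False
            interpolated[i0:i1] = False
            values[i0:i1] = np.nan
    period = 1.0 / rate
    iv = np.asarray(
        [[eda.start_time + i0 * period, eda.start_time + i1 * period]
         for i0, i1 in seg_bounds],
        dtype=float,
    ).reshape(-1, 2)
    return ProcessedSignal(
        source=eda,
        validity=sqi,
        values=values,
        retained=retained,
        interpolated=interpolated,
        segments=IntervalSet("retained", iv),
    )


class EdaQualityProcessor(BaseEstimator):
    """EDA artifact processor with the composite validity SQI.

    Attributes set by :meth:`transform`: ``validity_``, ``result_``.
    """

    def __init__(self, params: EdaQualityParams | None = None):
        self.params = params

    def fit(self, eda: UniformSeries | None = None, y=None) -> "EdaQualityProcessor":
        self.params_ = self.params or EdaQualityParams()
        return self

    def transform(
        self, eda: UniformSeries, wrist_sqi: SQISeries | None = None
    ) -> ProcessedSignal:
        """Build the validity SQI (all-on-body if no wrist SQI is given) and
        process the signal."""
        self.fit()
        if wrist_sqi is None:
            wrist_sqi = SQISeries("Wrist_SQI", eda.start_time,
                                  eda.sample_rate_hz, np.ones(len(eda), bool))
        self.validity_ = eda_validity_sqi(eda, wrist_sqi, self.params_)
        self.result_ = process_signal(eda, self.validity_, self.params_)
        return self.result_
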