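"""Activity intensity index from raw 3-axis accelerometry.

Implements the absolute form of Bai et al.'s activity index: per
non-overlapping epoch, the square root of the mean over the three axes of
the per-axis sample variance, optionally after subtracting a systematic
device-noise variance (truncated at zero).  At the 1-s default epoch this
yields a second-per-second intensity series in arbitrary units (g-scaled).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .timebase import UniformSeries, ValidationError

__all__ = ["activity_index_abs", "ActivityIndexABS"]


class ActivityIndexABS(BaseEstimator):
    """Epoch-wise activity index transformer.

    Parameters
    ----------
    epoch_s : float
        Epoch length in seconds (default 1); epochs tumble from the series
        start, and a partial trailing epoch is discarded.
    noise_var_g2 : float
        Systematic (device) noise variance in g² subtracted from each axis
        variance before averaging; 0 by default.
    """

    def __init__(self, epoch_s: float = 1.0, noise_var_g2: float = 0.0):
        self.epoch_s = epoch_s
        self.noise_var_g2 = noise_var_g2

    def fit(self, acc: UniformSeries | None = None, y=None) -> "ActivityIndexABS":
        if self.epoch_s <= 0:
            raise ValidationError("epoch_s must be positive")
        if self.noise_var_g2 < 0:
            raise ValidationError("noise_var_g2 must be non-negative")
        return self

    def transform(self, acc: UniformSeries) -> UniformSeries:
        """ACC (n, 3) in g → activity index series at ``1/epoch_s`` Hz."""
        self.fit()
        if acc.n_components != 3:
            raise ValidationError("activity index requires a 3-component ACC series")
        per_epoch = int(round(self.epoch_s * acc.sample_rate_hz))
        if per_epoch < 2:
            raise ValidationError("epoch must span at least 2 samples")
        n_epochs = len(acc) // per_epoch
        if n_epochs == 0:
            raise ValidationError("series shorter than one epoch")
        x = acc.values[: n_epochs * per_epoch].reshape(n_epochs, per_epoch, 3)
        axis_var = x.var(axis=1, ddof=1)  # (n_epochs, 3), unbiased
        ai = np.sqrt(np.clip((axis_var - self.noise_var_g2).mean(axis=1), 0.0, None))
        return UniformSeries("AI_ABS", acc.start_time, 1.0 / self.epoch_s,
                             ai, "a.u.")


def activity_index_abs(
    acc: UniformSeries, epoch_s: float = 1.0, noise_var_g2: float = 0.0
) -> UniformSeries:
    """Functional wrapper over :class:`ActivityIndexABS`."""
    return ActivityIndexABS(epoch_s=epoch_s, noise_var_g2=noise_var_g2).transform(acc)
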