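"""Centered rolling statistics with shrinking edge windows.

The window for output index ``i`` over a window of ``w`` samples is
``[i - (w-1)//2, i + w//2]`` inclusive, clipped to the series; edge windows
therefore shrink to the available samples.  O(n) via cumulative sums.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rolling_mean", "rolling_sd", "window_bounds"]


def window_bounds(n: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Half-open [lo, hi) window bounds per output index."""
    idx = np.arange(n)
    lo = np.clip(idx - (w - 1) // 2, 0, n)
    hi = np.clip(idx + w // 2 + 1, 0, n)
    return lo, hi


def rolling_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Centered rolling mean; works on (n,) or (n, k) arrays along axis 0."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    lo, hi = window_bounds(n, w)
    c = np.concatenate([np.zeros((1,) + x.shape[1:]), np.cumsum(x, axis=0)])
    m = (hi - lo).reshape((-1,) + (1,) * (x.ndim - 1))
    return (c[hi] - c[lo]) / m


def rolling_sd(x: np.ndarray, w: int, ddof: int = 1) -> np.ndarray:
    """Centered rolling standard deviation (sample SD by default).

    Windows with fewer than ``ddof + 1`` samples yield 0.  The input is
    centred on its global mean before accumulating, which keeps the
    cumulative sums well-conditioned for signals with large offsets.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n == 0:
        return x.copy()
    xc = x - x.mean(axis=0, keepdims=True)
    lo, hi = window_bounds(n, w)
    shape1 = (1,) + x.shape[1:]
    c1 = np.concatenate([np.zeros(shape1), np.cumsum(xc, axis=0)])
    c2 = np.concatenate([np.zeros(shape1), np.cumsum(xc * xc, axis=0)])
    m = (hi - lo).astype(float).reshape((-1,) + (1,) * (x.ndim - 1))
    s1 = c1[hi] - c1[lo]
    s2 = c2[hi] - c2[lo]
    var = np.zeros_like(s2)
    ok = m > ddof
    np.divide(s2 - s1 * s1 / m, m - ddof, out=var, where=ok)
    return np.sqrt(np.clip(var, 0.0, None))
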