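"""Block-gap bootstrapping for missing-data impact analysis.

Starting from a gap-free reference series over a window of interest, the
procedure repeatedly (1) removes contiguous blocks of samples so that an
exact target fraction of the data is retained, (2) recomputes the summary
metrics (median, 75th percentile, mean) on the retained samples, and
(3) summarises the spread of those metric values against the gap-free
reference.  Block-shaped gaps mimic non-wear bouts; the retention ratio is
an exact-count invariant, not a Bernoulli expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .timebase import IntervalSet, UniformSeries, ValidationError

__all__ = [
    "GapSpec",
    "MaskedSeries",
    "BootstrapResult",
    "induce_gaps",
    "window_metric",
    "bootstrap_spread",
    "spread_summary",
    "GapBootstrap",
]

METRICS = ("p50", "p75", "mean")
_MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass
class GapSpec:
    """How to carve gaps out of a series.

    strategy:
        ``single_block`` — one contiguous gap;
        ``multi_block`` — ``n_blocks`` near-equal gaps placed uniformly
        without overlap;
        ``bout_sampled`` — gap lengths drawn with replacement from an
        empirical non-wear bout-length list (seconds), last gap truncated
        to hit the exact removal count.
    retention_ratio:
        Fraction of samples kept, in (0, 1]; the number removed is exactly
        ``round((1 - retention_ratio) * n)``.
    """

    strategy: str = "multi_block"
    retention_ratio: float = 0.6
    n_blocks: int = 1
    bout_lengths_s: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strategy not in ("single_block", "multi_block", "bout_sampled"):
            raise ValidationError(f"unknown gap strategy {self.strategy!r}")
        if not 0.0 < self.retention_ratio <= 1.0:
            raise ValidationError("retention_ratio must be in (0, 1]")
        if self.n_blocks < 1:
            raise ValidationError("n_blocks must be >= 1")
        if self.strategy == "bout_sampled" and not len(self.bout_lengths_s):
            raise ValidationError("bout_sampled requires a bout_lengths_s list")


@dataclass
class MaskedSeries:
    """A uniform series with a per-sample missing mask (True = removed)."""

    series: UniformSeries
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != (len(self.series),):
            raise ValidationError("missing mask length mismatch")

    @property
    def retained_values(self) -> np.ndarray:
        return self.series.values[~self.missing]


@dataclass
class BootstrapResult:
    """Long-format bootstrap values plus the gap-free reference values."""

    rows: pd.DataFrame        # series_id, metric, ratio, iteration, value
    references: pd.DataFrame  # series_id, metric, reference_value


def _place_blocks(
    lengths: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Place blocks uniformly at random without overlap (rejection sampling).

    Blocks are kept at least one sample apart so each stays a distinct run.
    Returns the boolean removal mask.
    """
    mask = np.zeros(n, dtype=bool)
    placed: list[tuple[int, int]] = []
    attempts = 0
    for length in np.sort(lengths)[::-1]:  # longest first eases packing
        length = int(length)
        while True:
            attempts += 1
            if attempts > _MAX_PLACEMENT_ATTEMPTS:
                raise ValidationError(
                    "could not place gap blocks without overlap after "
                    f"{_MAX_PLACEMENT_ATTEMPTS} attempts; use fewer or "
                    "shorter blocks"
                )
            s = int(rng.integers(0, n - length + 1))
            if all(s + length < a or s > b for a, b in placed):
                placed.append((s - 1, s + length))  # pad so runs stay separate
                mask[s:s + length] = True
                break
    return mask


def induce_gaps(
    series: UniformSeries, spec: GapSpec, rng_seed
) -> tuple[MaskedSeries, IntervalSet]:
    """Remove exactly ``round((1 - retention_ratio) * n)`` samples in blocks.

    ``rng_seed`` may be an int, a ``SeedSequence`` or a ``Generator``.
    Returns the masked series and the removed runs as half-open intervals.
    """
    n = len(series)
    if n < 10:
        raise ValidationError("need at least 10 samples to induce gaps")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    n_remove = int(round((1.0 - spec.retention_ratio) * n))
    if n_remove > n - 1:
        raise ValidationError("requested removal leaves no samples")
    if n_remove == 0:
        masked = MaskedSeries(series, np.zeros(n, dtype=bool))
        return masked, IntervalSet("gaps")

    if spec.strategy == "single_block":
        lengths = np.array([n_remove])
    elif spec.strategy == "multi_block":
        k = min(spec.n_blocks, n_remove)
        base, extra = divmod(n_remove, k)
        lengths = np.array([base + 1] * extra + [base] * (k - extra))
    else:  # bout_sampled
        rate = series.sample_rate_hz
        lens: list[int] = []
        total = 0
        while total < n_remove:
            bout = float(rng.choice(np.asarray(spec.bout_lengths_s, dtype=float)))
            length = max(int(round(bout * rate)), 1)
            length = min(length, n_remove - total)
            lens.append(length)
            total += length
        lengths = np.array(lens)

    mask = _place_blocks(lengths, n, rng)
    assert mask.sum() == n_remove
    period = 1.0 / series.sample_rate_hz
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    iv = np.column_stack([series.start_time + edges[0::2] * period,
                          series.start_time + edges[1::2] * period])
    return MaskedSeries(series, mask), IntervalSet("gaps", iv)


def window_metric(series, metric: str) -> float:
    """Summary metric over the non-missing samples of a window.

    Accepts a :class:`MaskedSeries` or a plain :class:`UniformSeries`
    (no mask).  Percentiles use linear interpolation between order
    statistics.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {METRICS}")
    if isinstance(series, MaskedSeries):
        vals = series.retained_values
    else:
        vals = np.asarray(series.values if isinstance(series, UniformSeries)
                          else series, dtype=float)
    if vals.size == 0:
        raise ValidationError("no non-missing samples in window")
    if metric == "mean":
        return float(np.mean(vals))
    q = 50.0 if metric == "p50" else 75.0
    return float(np.percentile(vals, q))


def bootstrap_spread(
    reference: UniformSeries,
    ratios,
    n_iter: int,
    metrics=METRICS,
    spec_template: GapSpec | None = None,
    master_seed: int = 0,
    series_id: str | None = None,
) -> BootstrapResult:
    """Gap bootstrap over a grid of retention ratios.

    Each (ratio, iteration) pair draws gaps from an independent substream of
    ``master_seed``, so results are reproducible and independent of
    evaluation order.  Reference metric values are computed once on the
    intact series.
    """
    spec_template = spec_template or GapSpec()
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    sid = series_id or reference.channel_name
    refs = pd.DataFrame(
        {
            "series_id": sid,
            "metric": list(metrics),
            "reference_value": [window_metric(reference, m) for m in metrics],
        }
    )
    records = []
    for ri, ratio in enumerate(ratios):
        spec = GapSpec(
            strategy=spec_template.strategy,
            retention_ratio=float(ratio),
            n_blocks=spec_template.n_blocks,
            bout_lengths_s=spec_template.bout_lengths_s,
        )
        for it in range(n_iter):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(master_seed), ri, it])
            )
            try:
                masked, _ = induce_gaps(reference, spec, rng)
            except ValidationError as exc:
                raise ValidationError(
                    f"gap induction failed at ratio={ratio}, iteration={it}: {exc}"
                ) from exc
            for m in metrics:
                records.append((sid, m, float(ratio), it,
                                window_metric(masked, m)))
    rows = pd.DataFrame(
        records, columns=["series_id", "metric", "ratio", "iteration", "value"]
    )
    return BootstrapResult(rows=rows, references=refs)


def spread_summary(
    res: BootstrapResult, epsilon: float | None = None
) -> pd.DataFrame:
    """Per (series, metric, ratio): bias, SD, central 90 % interval, and —
    when ``epsilon`` is given — the fraction of iterations within ±ε of the
    gap-free reference."""
    if res.rows.empty:
        raise ValidationError("empty bootstrap result")
    ref_map = res.references.set_index(["series_id", "metric"])["reference_value"]
    out = []
    for (sid, m, ratio), grp in res.rows.groupby(
        ["series_id", "metric", "ratio"], sort=True
    ):
        ref = float(ref_map.loc[(sid, m)])
        v = grp["value"].to_numpy()
        row = {
            "series_id": sid,
            "metric": m,
            "ratio": ratio,
            "reference_value": ref,
            "bias": float(np.mean(v) - ref),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "q05": float(np.percentile(v, 5)),
            "q95": float(np.percentile(v, 95)),
        }
        if epsilon is not None:
            row["frac_within_eps"] = float(np.mean(np.abs(v - ref) <= epsilon))
        out.append(row)
    return pd.DataFrame(out)


class GapBootstrap(BaseEstimator):
    """Estimator wrapper: fit on a gap-free reference series.

    Attributes set by :meth:`fit`: ``result_`` (long table),
    ``references_``, ``summary_``.
    """

    def __init__(
        self,
        ratios=(0.9, 0.8, 0.7, 0.6),
        n_iter: int = 100,
        metrics=METRICS,
        strategy: str = "multi_block",
        n_blocks: int = 3,
        bout_lengths_s=(),
        master_seed: int = 0,
        epsilon: float | None = None,
    ):
        self.ratios = ratios
        self.n_iter = n_iter
        self.metrics = metrics
        self.strategy = strategy
        self.n_blocks = n_blocks
        self.bout_lengths_s = bout_lengths_s
        self.master_seed = master_seed
        self.epsilon = epsilon

    def fit(self, reference: UniformSeries, y=None) -> "GapBootstrap":
        spec = GapSpec(strategy=self.strategy, n_blocks=self.n_blocks,
                       bout_lengths_s=list(self.bout_lengths_s))
        res = bootstrap_spread(
            reference, self.ratios, self.n_iter, self.metrics,
            spec_template=spec, master_seed=self.master_seed,
        )
        self.result_ = res.rows
        self.references_ = res.references
        self.summary_ = spread_summary(res, epsilon=self.epsilon)
        return self
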