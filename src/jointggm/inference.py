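"""Significance machinery for comparing conditions.

Global-metric differences are assessed by non-overlap of Bonferroni-
adjusted equal-tailed credible intervals of the metric posteriors; nodal
metrics (betweenness, participation coefficient), whose distributions
across nodes are not normal, by the Wilcoxon signed-rank test; and
edge-level differences by credible intervals of draw-wise differences of
partial correlations.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import stats

from jointggm.graph_metrics import MetricPosterior

#: Default number of simultaneous comparisons: baseline-vs-follow-up for
#: each of 5 metrics in 2 cohorts (10) plus cohort-vs-cohort for each
#: metric (5).
DEFAULT_M = 15


@dataclasses.dataclass
class ComparisonResult:
    quantity: str
    groups: tuple[str, str]
    interval_a: tuple[float, float]
    interval_b: tuple[float, float]
    adjusted_alpha: float
    significant: bool
    p_value: float | None = None


def bonferroni_alpha(alpha: float, m: int = DEFAULT_M) -> float:
    """Family-wise adjusted level alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def _equal_tailed(values: np.ndarray, adjusted_alpha: float) -> tuple[float, float]:
    lo, hi = np.quantile(values, [adjusted_alpha / 2, 1 - adjusted_alpha / 2])
    return float(lo), float(hi)


def credible_interval_comparison(
    post_a: MetricPosterior,
    post_b: MetricPosterior,
    adjusted_alpha: float,
) -> ComparisonResult:
    """Significant iff the 100(1-alpha)% credible intervals do not overlap.

    Intervals are equal-tailed empirical quantiles; touching endpoints
    count as overlap (conservative).  Requires enough retained draws to
    resolve the tail quantiles (>= 2 / adjusted_alpha).
    """
    needed = math.ceil(2.0 / adjusted_alpha)
    for post in (post_a, post_b):
        if post.values.size < needed:
            raise ValueError(
                f"{post.values.size} retained draws cannot resolve "
                f"alpha={adjusted_alpha:g} quantiles; run >= {needed} iterations"
            )
    ia = _equal_tailed(post_a.values, adjusted_alpha)
    ib = _equal_tailed(post_b.values, adjusted_alpha)
    significant = ia[1] < ib[0] or ib[1] < ia[0]
    return ComparisonResult(
        quantity=post_a.metric_name,
        groups=(post_a.condition_id, post_b.condition_id),
        interval_a=ia,
        interval_b=ib,
        adjusted_alpha=adjusted_alpha,
        significant=bool(significant),
    )


def wilcoxon_signed_rank(
    paired_values_a: np.ndarray, paired_values_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired nodal values.

    Zero differences are dropped; the null distribution is exact for
    n <= 25 without ties, else a tie-corrected normal approximation.
    All-zero differences define p = 1 with a warning.
    """
    a = np.asarray(paired_values_a, dtype=float)
    b = np.asarray(paired_values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must share length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all differences are zero; p defined as 1", stacklevel=2)
        return 0.0, 1.0
    if d.size < 6:
        raise ValueError("need >= 6 nonzero differences")
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=False)
    return float(res.statistic), float(res.pvalue)


def edge_difference_rate(
    summary,
    cond_a: str,
    cond_b: str,
    adjusted_alpha: float,
) -> tuple[set[tuple[int, int]], float]:
    """Edges whose partial-correlation difference excludes 0, and their rate.

    Per node pair, an equal-tailed credible interval of the draw-wise
    difference of partial correlations between the two conditions is
    formed at level 1 - adjusted_alpha; pairs whose interval excludes zero
    are flagged.  Returns the flagged pair set and 100 * flagged / pairs.
    """
    if summary.partial_draws is None or summary.partial_draws.size == 0:
        raise ValueError("no stored partial-correlation draws")
    ka = summary.condition_ids.index(cond_a)
    kb = summary.condition_ids.index(cond_b)
    diff = summary.partial_draws[:, :, ka].astype(float) - summary.partial_draws[
        :, :, kb
    ].astype(float)
    lo, hi = np.quantile(diff, [adjusted_alpha / 2, 1 - adjusted_alpha / 2], axis=0)
    flagged_idx = np.flatnonzero((lo > 0) | (hi < 0))
    pairs = {
        (int(summary.pair_rows[i]), int(summary.pair_cols[i])) for i in flagged_idx
    }
    rate = 100.0 * len(pairs) / diff.shape[1]
    return pairs, rate
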