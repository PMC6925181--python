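"""Hub identification and test-retest reproducibility statistics.

Hubs are nodes whose normalized betweenness exceeds the mean by c standard
deviations (c = 1.5 by default, sample sd).  Cross-visit hub agreement is
quantified by Cohen's kappa, swept over the full range of betweenness
thresholds; nodal-metric reliability across visits by the one-way
random-effects intraclass correlation ICC(1,1).
"""

from __future__ import annotations

import warnings

import numpy as np


def identify_hubs(scores: np.ndarray, c: float = 1.5) -> set[int]:
    """Nodes with score strictly above mean + c * sd (sample sd, ddof=1)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 nodes")
    sd = scores.std(ddof=1)
    if sd == 0.0:
        warnings.warn("constant scores: no hubs identifiable", stacklevel=2)
        return set()
    threshold = scores.mean() + c * sd
    return set(np.flatnonzero(scores > threshold).tolist())


def kappa(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Cohen's kappa for two binary labelings.

    kappa = (p_o - p_e) / (1 - p_e) with marginal-product expected
    agreement p_e; when p_e = 1 both labelings are degenerate on the same
    category, agreement is certain, and kappa is defined as 1.
    """
    a = np.asarray(labels_a).astype(int)
    b = np.asarray(labels_b).astype(int)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("labelings must share length >= 2")
    n = a.size
    p_o = float((a == b).mean())
    pa1, pb1 = a.mean(), b.mean()
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def kappa_curve(
    scores_visit1: np.ndarray, scores_visit2: np.ndarray
) -> list[tuple[float, float]]:
    """Hub-agreement kappa at every observed score threshold.

    Thresholds sweep the sorted union of the two score vectors; at each, a
    node is a hub in a visit when its score >= threshold.  Thresholds where
    either visit is all-hub or no-hub give NaN (agreement is degenerate).
    The curve depends on the scores only through ranks, so it is invariant
    to monotone transforms.
    """
    s1 = np.asarray(scores_visit1, dtype=float)
    s2 = np.asarray(scores_visit2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("score vectors must share length")
    out = []
    for t in np.unique(np.concatenate([s1, s2])):
        h1 = s1 >= t
        h2 = s2 >= t
        if h1.all() or h2.all() or not h1.any() or not h2.any():
            out.append((float(t), float("nan")))
        else:
            out.append((float(t), kappa(h1, h2)))
    return out


def icc_oneway(values: np.ndarray, variant: str = "oneway") -> float:
    """Intraclass correlation of a nodes x visits matrix.

    ``variant="oneway"`` is the one-way random-effects ICC(1,1),
    (MSB - MSW) / (MSB + (k-1) MSW) with nodes as targets and visits as
    repeated measures.  ``variant="consistency"`` is the two-way
    consistency form ICC(3,1), which removes the visit (session) mean
    before comparing.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need a nodes x visits matrix with >=3 nodes, >=2 visits")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing values not supported")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance; ICC undefined")
    row_means = x.mean(axis=1)
    ssb = k * ((row_means - grand) ** 2).sum()
    msb = ssb / (n - 1)
    if variant == "oneway":
        ssw = ((x - row_means[:, None]) ** 2).sum()
        msw = ssw / (n * (k - 1))
        return float((msb - msw) / (msb + (k - 1) * msw))
    if variant == "consistency":
        col_means = x.mean(axis=0)
        sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        return float((msb - mse) / (msb + (k - 1) * mse))
    raise ValueError("variant must be 'oneway' or 'consistency'")
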