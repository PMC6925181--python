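"""AR prewhitening and condition-level pooling.

Gaussian graphical models assume independent rows; fMRI-like series are
temporally autocorrelated.  Each node's series is therefore replaced by the
residuals of a per-node autoregressive fit before the group-level fit.
Subjects of one condition are column-standardized individually and stacked
vertically; the stacked cross-product (scatter) matrix and row count are
the sufficient statistics consumed by the samplers.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from statsmodels.tsa.ar_model import AutoReg, ar_select_order


@dataclasses.dataclass
class ConditionData:
    """Pooled prewhitened data for one condition (cohort x visit)."""

    condition_id: str
    matrix: np.ndarray  # stacked standardized residual rows x node_count
    n_rows: int
    scatter: np.ndarray  # matrix.T @ matrix
    subject_index: np.ndarray  # row -> subject ordinal

    @property
    def node_count(self) -> int:
        return self.matrix.shape[1]


def prewhiten_ar(
    series: np.ndarray,
    max_order: int = 1,
    order_selection: str = "fixed",
) -> tuple[np.ndarray, list[dict]]:
    """Fit AR(q) per column by OLS and return aligned residuals.

    With ``order_selection="fixed"`` every node uses q = ``max_order``; with
    ``"aic"`` q minimizes AIC over 0..``max_order``.  Residuals of all
    columns are aligned by dropping the first ``max_order`` rows, so the
    returned matrix is rectangular with T - max_order rows.

    Returns the residual matrix and, per node, the fitted order and
    coefficients.
    """
    series = np.asarray(series, dtype=float)
    T, p = series.shape
    if order_selection not in ("fixed", "aic"):
        raise ValueError("order_selection must be 'fixed' or 'aic'")
    if T <= max_order + 2:
        raise ValueError(f"series too short (T={T}) for max_order={max_order}")
    resid = np.empty((T - max_order, p))
    info: list[dict] = []
    for j in range(p):
        x = series[:, j]
        if np.ptp(x) == 0.0:
            raise ValueError(f"node {j} is constant; cannot prewhiten")
        if order_selection == "fixed":
            q = max_order
        else:
            sel = ar_select_order(x, maxlag=max_order, ic="aic", trend="c")
            q = 0 if not sel.ar_lags else max(sel.ar_lags)
        if q == 0:
            r = x - x.mean()
            coefs = np.empty(0)
        else:
            fit = AutoReg(x, lags=q, trend="c").fit()
            r = fit.resid  # length T - q
            coefs = fit.params[1:]
        resid[:, j] = r[-(T - max_order):]
        info.append({"node": j, "order": q, "coefficients": coefs})
    return resid, info


def standardize_and_stack(
    residuals: list[np.ndarray],
    condition_id: str = "",
    subject_ids: list[str] | None = None,
) -> ConditionData:
    """Column-standardize each subject's residuals, then stack vertically.

    Per-subject standardization (mean 0, variance 1 per column) prevents one
    subject's variance from dominating the pooled scatter matrix.
    """
    if not residuals:
        raise ValueError("no subjects supplied")
    p = residuals[0].shape[1]
    blocks: list[np.ndarray] = []
    subject_index: list[int] = []
    for s, r in enumerate(residuals):
        r = np.asarray(r, dtype=float)
        if r.shape[1] != p:
            raise ValueError(f"subject {s}: node count {r.shape[1]} != {p}")
        sd = r.std(axis=0)
        if np.any(sd == 0.0):
            bad = int(np.argmin(sd))
            raise ValueError(f"subject {s}: column {bad} has zero variance")
        blocks.append((r - r.mean(axis=0)) / sd)
        subject_index.extend([s] * r.shape[0])
    stacked = np.vstack(blocks)
    return ConditionData(
        condition_id=condition_id,
        matrix=stacked,
        n_rows=stacked.shape[0],
        scatter=stacked.T @ stacked,
        subject_index=np.asarray(subject_index),
    )


def prepare_condition(
    dataset,
    condition_id: str,
    max_order: int = 1,
    order_selection: str = "fixed",
) -> ConditionData:
    """Prewhiten every subject of one condition and pool the residuals."""
    subs = dataset.subjects(condition_id)
    if not subs:
        raise ValueError(f"no subjects for condition {condition_id}")
    resids = [prewhiten_ar(x, max_order, order_selection)[0] for _, x in subs]
    return standardize_and_stack(
        resids, condition_id=condition_id, subject_ids=[sid for sid, _ in subs]
    )
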