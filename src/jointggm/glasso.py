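"""Separate per-condition estimation: the graphical-lasso comparison arm.

Each condition's precision matrix is estimated independently by maximizing
log det Omega - tr(S Omega) - penalty * ||Omega||_1,off.  For a comparison
on equal footing with the joint fit, the penalty is tuned by bisection so
the achieved network density matches a target (density is monotone
non-increasing in the penalty).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.covariance import graphical_lasso as _sk_glasso
from sklearn.exceptions import ConvergenceWarning

from jointggm.preprocess import ConditionData

SUPPORT_TOL = 1e-6


@dataclasses.dataclass
class GlassoFit:
    penalty: float
    precision: np.ndarray
    adjacency: np.ndarray  # 0/1 support of off-diagonals above SUPPORT_TOL
    density_pct: float
    lambda_trace: list[tuple[float, float]] = dataclasses.field(default_factory=list)


def _fit_to_result(precision: np.ndarray, penalty: float) -> GlassoFit:
    p = precision.shape[0]
    off = np.abs(precision) > SUPPORT_TOL
    np.fill_diagonal(off, False)
    adj = (off | off.T).astype(np.int8)
    e = int(adj.sum()) // 2
    return GlassoFit(
        penalty=penalty,
        precision=precision,
        adjacency=adj,
        density_pct=100.0 * e / (p * (p - 1) / 2),
    )


def graphical_lasso_fit(
    scatter: np.ndarray,
    n_rows: int,
    penalty: float,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> GlassoFit:
    """L1-penalized precision fit from a scatter matrix and row count."""
    S = np.asarray(scatter, dtype=float) / n_rows
    p = S.shape[0]
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    if penalty == 0.0:
        if n_rows <= p:
            raise ValueError("unpenalized MLE needs n_rows > p")
        return _fit_to_result(np.linalg.inv(S), 0.0)
    last_exc: Exception | None = None
    for mode in ("cd", "lars"):  # lars is a more robust fallback on hard penalties
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                _, precision = _sk_glasso(
                    S, alpha=penalty, tol=tol, max_iter=max_iter, mode=mode
                )
                return _fit_to_result(precision, penalty)
            except (ConvergenceWarning, FloatingPointError) as exc:
                last_exc = exc
    raise RuntimeError(
        f"graphical lasso failed to converge at penalty={penalty:g}: {last_exc}"
    ) from last_exc


def density_matched_fit(
    condition_data: ConditionData,
    target_density: float,
    tol_density: float = 0.5,
    penalty_bounds: tuple[float, float] | None = None,
    max_bisect: int = 50,
) -> GlassoFit:
    """Bisection on the penalty until the achieved density matches the target.

    ``target_density`` is in percent of possible edges.  Returns the
    closest fit found, with the (penalty, density) trace logged on the
    result; raises when the target is unreachable within the bracket.
    """
    if not 0 < target_density < 100:
        raise ValueError("target_density must lie in (0, 100)")
    S = condition_data.scatter / condition_data.n_rows
    off = np.abs(S - np.diag(np.diag(S)))
    if penalty_bounds is None:
        penalty_bounds = (1e-4, float(off.max()) + 1e-6)
    lo, hi = penalty_bounds

    trace: list[tuple[float, float]] = []

    def density_at(lam: float) -> tuple[float, GlassoFit]:
        fit = graphical_lasso_fit(condition_data.scatter, condition_data.n_rows, lam)
        trace.append((lam, fit.density_pct))
        return fit.density_pct, fit

    d_lo, fit_lo = density_at(lo)
    if d_lo + tol_density < target_density:
        raise ValueError(
            f"target density {target_density}% unreachable: density at "
            f"penalty={lo:g} is only {d_lo:.2f}%"
        )
    d_hi, fit_hi = density_at(hi)
    best = min((fit_lo, fit_hi), key=lambda f: abs(f.density_pct - target_density))
    for _ in range(max_bisect):
        if abs(best.density_pct - target_density) <= tol_density:
            break
        mid = 0.5 * (lo + hi)
        d_mid, fit_mid = density_at(mid)
        if abs(fit_mid.density_pct - target_density) < abs(
            best.density_pct - target_density
        ):
            best = fit_mid
        if d_mid > target_density:
            lo = mid  # too dense -> increase penalty side
        else:
            hi = mid
    best.lambda_trace = trace
    return best
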