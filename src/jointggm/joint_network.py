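"""Joint MCMC estimation of multiple sparse precision matrices.

K condition-specific Gaussian graphical models are fit jointly.  Each
off-diagonal precision entry omega_ijk carries a continuous spike-and-slab
prior: N(0, v0^2) when the edge indicator z_ijk = 0 (spike) and
N(0, v1^2) when z_ijk = 1 (slab), with v0 << v1.  Diagonals carry an
exponential prior with rate lambda_d.  The edge-inclusion probability is
pooled across conditions through a logistic link

    logit pi_ijk = theta_ij + delta_ijk,

where theta_ij is shared by all conditions and the differential effects
delta_ijk are centered to sum to zero over k for identifiability.  theta
and delta are updated by Polya-Gamma-augmented conjugate Gaussian steps;
each precision matrix is updated column-by-column with a block draw
(multivariate normal off-diagonal block plus a gamma draw for the Schur
complement of the diagonal) that preserves positive definiteness at every
accepted state.

Draw-order contract (what a fixed seed reproduces): per iteration, for each
condition k in order and each column j in order, (1) p-1 standard normals
for the off-diagonal block, (2) one gamma variate for the diagonal; then
one link sweep: (3) uniforms of shape (pairs, K) for z, (4) standard
exponentials of shape (pairs, K, n_terms) for the Polya-Gamma draws,
(5) standard normals of shape (pairs,) for theta, (6) standard normals of
shape (pairs, K) for delta.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from jointggm._polya_gamma import pg_draw
from jointggm.graph_metrics import BinaryNetwork
from jointggm.preprocess import ConditionData

LOGIT_CLAMP = 30.0
DIVERGENCE_LIMIT = 1e6


@dataclasses.dataclass
class JointGGMConfig:
    """Hyperparameters and run controls for the joint sampler.

    v0/v1 are the spike and slab standard deviations on off-diagonal
    precision entries (unitless; the data are standardized), lambda_diag
    the rate of the exponential prior on diagonals.  theta_prior_mean = -2
    encodes an a-priori sparse network (prior edge probability ~0.12 at
    delta = 0); delta_prior_sd = inf disables pooling and yields separate
    per-condition fits.
    """

    v0: float = 0.02
    v1: float = 1.0
    lambda_diag: float = 1.0
    theta_prior_mean: float = -2.0
    theta_prior_sd: float = 1.0
    delta_prior_sd: float = 1.0
    n_iter: int = 2000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0
    edge_call_threshold: float = 0.5
    pg_terms: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.v0 < self.v1:
            raise ValueError("require 0 < v0 < v1")
        if not self.n_iter > self.burn_in >= 0:
            raise ValueError("require n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 < self.edge_call_threshold < 1:
            raise ValueError("edge_call_threshold must lie in (0, 1)")
        if self.lambda_diag <= 0:
            raise ValueError("lambda_diag must be positive")


@dataclasses.dataclass
class MCMCState:
    """Current sampler state: K precision matrices plus the link layer."""

    omegas: list[np.ndarray]  # K symmetric PD (p, p)
    z: np.ndarray  # (pairs, K) slab indicators in {0, 1}
    theta: np.ndarray  # (pairs,) shared logit effects
    delta: np.ndarray  # (pairs, K), rows sum to zero
    pair_rows: np.ndarray  # upper-triangle row index per pair
    pair_cols: np.ndarray

    @property
    def node_count(self) -> int:
        return self.omegas[0].shape[0]

    @property
    def n_conditions(self) -> int:
        return len(self.omegas)


@dataclasses.dataclass
class PosteriorSummary:
    """Aggregated MCMC output for all conditions."""

    condition_ids: list[str]
    node_count: int
    pip: dict[str, np.ndarray]  # posterior inclusion probability (p, p)
    partial_mean: dict[str, np.ndarray]  # posterior mean partial corr (p, p)
    z_draws: np.ndarray  # (n_kept, pairs, K) uint8
    partial_draws: np.ndarray  # (n_kept, pairs, K) float32
    pair_rows: np.ndarray
    pair_cols: np.ndarray
    config: JointGGMConfig
    diagnostics: dict

    @property
    def n_kept(self) -> int:
        return self.z_draws.shape[0]

    def _k(self, condition_id: str) -> int:
        return self.condition_ids.index(condition_id)

    def partial_credible_interval(
        self, condition_id: str, level: float = 0.95
    ) -> tuple[np.ndarray, np.ndarray]:
        """Equal-tailed per-pair credible intervals of the partial correlation.

        Returns (lo, hi) as symmetric (p, p) matrices with unit diagonal.
        """
        k = self._k(condition_id)
        a = (1.0 - level) / 2.0
        qs = np.quantile(self.partial_draws[:, :, k].astype(float), [a, 1 - a], axis=0)
        lo = _pairs_to_matrix(qs[0], self.pair_rows, self.pair_cols, self.node_count, diag=1.0)
        hi = _pairs_to_matrix(qs[1], self.pair_rows, self.pair_cols, self.node_count, diag=1.0)
        return lo, hi

    def iteration_networks(self, condition_id: str, rsn_labels=None):
        """Yield the per-iteration sampled structures as binary networks."""
        k = self._k(condition_id)
        p = self.node_count
        labels = list(rsn_labels) if rsn_labels is not None else ["unknown"] * p
        for t in range(self.n_kept):
            adj = _pairs_to_matrix(
                self.z_draws[t, :, k].astype(np.int8), self.pair_rows, self.pair_cols, p
            )
            yield BinaryNetwork(adjacency=adj, rsn_labels=labels)


def _pairs_to_matrix(values, rows, cols, p, diag=0.0):
    m = np.full((p, p), 0.0, dtype=float if not np.issubdtype(np.asarray(values).dtype, np.integer) else np.asarray(values).dtype)
    m[rows, cols] = values
    m[cols, rows] = values
    np.fill_diagonal(m, diag)
    return m


def partial_correlation(omega: np.ndarray) -> np.ndarray:
    """rho_ij = -omega_ij / sqrt(omega_ii * omega_jj), unit diagonal."""
    d = np.diag(omega)
    if np.any(d <= 0):
        raise ValueError("precision matrix has non-positive diagonal")
    s = 1.0 / np.sqrt(d)
    rho = -omega * np.outer(s, s)
    np.fill_diagonal(rho, 1.0)
    return rho


def initialize_state(
    condition_data: list[ConditionData], config: JointGGMConfig
) -> MCMCState:
    """Diagonal PD start: inverse sample variances plus a small ridge."""
    if not condition_data:
        raise ValueError("need at least one condition")
    p = condition_data[0].node_count
    for cd in condition_data:
        if cd.node_count != p:
            raise ValueError("conditions disagree on node count")
        if cd.n_rows <= 0:
            raise ValueError(f"condition {cd.condition_id} has no rows")
    K = len(condition_data)
    rows, cols = np.triu_indices(p, 1)
    omegas = []
    for cd in condition_data:
        var = np.diag(cd.scatter) / cd.n_rows
        omegas.append(np.diag(1.0 / (var + 1e-6)))
    n_pairs = len(rows)
    return MCMCState(
        omegas=omegas,
        z=np.zeros((n_pairs, K), dtype=np.uint8),
        theta=np.full(n_pairs, config.theta_prior_mean),
        delta=np.zeros((n_pairs, K)),
        pair_rows=rows,
        pair_cols=cols,
    )


def update_precision_column(
    state: MCMCState,
    k: int,
    j: int,
    condition_data: ConditionData,
    config: JointGGMConfig,
    rng: np.random.Generator,
) -> None:
    """Redraw row/column j of Omega_k from its full conditional (in place).

    With S the scatter and n the row count, the off-diagonal block beta has
    conditional N(-C s_12, C), C = ((s_jj + lambda_d) Omega11^{-1} + D^{-1})^{-1}
    where D is the diagonal of spike/slab prior variances, and the Schur
    complement gamma = omega_jj - beta' Omega11^{-1} beta has conditional
    Gamma(n/2 + 1, rate (s_jj + lambda_d) / 2); gamma > 0 keeps Omega_k PD.
    """
    om = state.omegas[k]
    p = om.shape[0]
    idx = np.arange(p) != j
    S = condition_data.scatter
    n = condition_data.n_rows
    omega11 = om[np.ix_(idx, idx)]
    omega11_inv = np.linalg.inv(omega11)
    s12 = S[idx, j]
    sjj = S[j, j]

    # Spike/slab prior variances for the pairs touching node j, in the
    # order of the reduced index set.
    v = np.where(_pair_indicator_for_column(state, k, j), config.v1, config.v0)
    c_inv = (sjj + config.lambda_diag) * omega11_inv + np.diag(1.0 / v**2)
    try:
        chol_cinv = np.linalg.cholesky(c_inv)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            f"non-PD conditional covariance at condition {k}, column {j}; "
            "check v0/lambda_diag configuration"
        ) from exc
    # beta = mu + C^{1/2} u with C = (L L')^{-1}: solve L' w = u, then C s.
    u = rng.standard_normal(p - 1)
    mu = -np.linalg.solve(c_inv, s12)
    beta = mu + np.linalg.solve(chol_cinv.T, u)
    gamma = rng.gamma(n / 2.0 + 1.0, 2.0 / (sjj + config.lambda_diag))

    om[idx, j] = beta
    om[j, idx] = beta
    om[j, j] = gamma + beta @ omega11_inv @ beta


def _pair_indicator_for_column(state: MCMCState, k: int, j: int) -> np.ndarray:
    """Slab indicators for pairs (i, j), i != j, ordered by the reduced index."""
    p = state.node_count
    zmat = _pairs_to_matrix(state.z[:, k], state.pair_rows, state.pair_cols, p)
    return zmat[np.arange(p) != j, j].astype(bool)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def update_link_and_indicators(
    state: MCMCState, config: JointGGMConfig, rng: np.random.Generator
) -> None:
    """Redraw z, then theta and delta via Polya-Gamma augmentation (in place).

    z_ijk is Bernoulli with odds pi * N(omega; 0, v1^2) against
    (1 - pi) * N(omega; 0, v0^2), logit pi = theta_ij + delta_ijk (clamped
    to +/-30).  Given z, (theta, delta) get conjugate Gaussian updates with
    PG(1, psi) auxiliaries; delta is re-centered to sum to zero over
    conditions after the draw.
    """
    rows, cols = state.pair_rows, state.pair_cols
    K = state.n_conditions
    W = np.stack([om[rows, cols] for om in state.omegas], axis=1)  # (pairs, K)

    psi = np.clip(state.theta[:, None] + state.delta, -LOGIT_CLAMP, LOGIT_CLAMP)
    # log odds slab : spike
    log_odds = (
        psi
        + (-0.5 * (W / config.v1) ** 2 - math.log(config.v1))
        - (-0.5 * (W / config.v0) ** 2 - math.log(config.v0))
    )
    state.z = (rng.random(psi.shape) < _sigmoid(log_odds)).astype(np.uint8)

    pg = pg_draw(psi, rng, config.pg_terms)
    kap = state.z.astype(float) - 0.5

    prior_prec_theta = 1.0 / config.theta_prior_sd**2
    prec_t = pg.sum(axis=1) + prior_prec_theta
    mean_t = (
        (kap - pg * state.delta).sum(axis=1)
        + config.theta_prior_mean * prior_prec_theta
    ) / prec_t
    state.theta = mean_t + rng.standard_normal(len(prec_t)) / np.sqrt(prec_t)

    prior_prec_delta = 0.0 if np.isinf(config.delta_prior_sd) else 1.0 / config.delta_prior_sd**2
    prec_d = pg + prior_prec_delta
    mean_d = (kap - pg * state.theta[:, None]) / prec_d
    delta = mean_d + rng.standard_normal(pg.shape) / np.sqrt(prec_d)
    state.delta = delta - delta.mean(axis=1, keepdims=True) if K > 1 else np.zeros_like(delta)


def run_mcmc(
    condition_data: list[ConditionData],
    config: JointGGMConfig,
    check_pd: bool = False,
) -> PosteriorSummary:
    """Run the joint Gibbs sampler and aggregate post-burn-in draws.

    One iteration sweeps every condition's columns, then the link layer.
    Retained iterations (post burn-in, thinned) store the sampled structures
    z and the partial-correlation values of the sampled precision matrices.
    Fixing ``config.seed`` reproduces the output bit-identically.
    """
    state = initialize_state(condition_data, config)
    rng = np.random.default_rng(config.seed)
    K = state.n_conditions
    p = state.node_count
    rows, cols = state.pair_rows, state.pair_cols

    kept_z: list[np.ndarray] = []
    kept_pc: list[np.ndarray] = []
    edge_trace = np.zeros((config.n_iter, K))

    for it in range(1, config.n_iter + 1):
        for k in range(K):
            for j in range(p):
                update_precision_column(state, k, j, condition_data[k], config, rng)
            if np.max(np.abs(state.omegas[k])) > DIVERGENCE_LIMIT:
                raise RuntimeError(
                    f"divergence at iteration {it}, condition {k}: "
                    "|omega| exceeded 1e6"
                )
            if check_pd:
                np.linalg.cholesky(state.omegas[k])
        update_link_and_indicators(state, config, rng)
        edge_trace[it - 1] = state.z.sum(axis=0)
        if it > config.burn_in and (it - config.burn_in - 1) % config.thin == 0:
            kept_z.append(state.z.copy())
            pc = np.stack(
                [partial_correlation(om)[rows, cols] for om in state.omegas], axis=1
            )
            kept_pc.append(pc.astype(np.float32))

    z_draws = np.stack(kept_z)
    pc_draws = np.stack(kept_pc)
    cids = [cd.condition_id for cd in condition_data]
    pip = {}
    pmean = {}
    for k, cid in enumerate(cids):
        pip[cid] = _pairs_to_matrix(z_draws[:, :, k].mean(axis=0), rows, cols, p)
        pmean[cid] = _pairs_to_matrix(
            pc_draws[:, :, k].astype(float).mean(axis=0), rows, cols, p, diag=1.0
        )
    return PosteriorSummary(
        condition_ids=cids,
        node_count=p,
        pip=pip,
        partial_mean=pmean,
        z_draws=z_draws,
        partial_draws=pc_draws,
        pair_rows=rows,
        pair_cols=cols,
        config=config,
        diagnostics={
            "edge_count_trace": edge_trace,
            "n_kept": z_draws.shape[0],
        },
    )


def call_edges(
    summary: PosteriorSummary,
    threshold: float | None = None,
    rsn_labels=None,
) -> dict[str, BinaryNetwork]:
    """Median-probability-model edge calling: adjacency = 1 iff pip > threshold."""
    if threshold is None:
        threshold = summary.config.edge_call_threshold
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    p = summary.node_count
    labels = list(rsn_labels) if rsn_labels is not None else ["unknown"] * p
    nets = {}
    for cid in summary.condition_ids:
        adj = (summary.pip[cid] > threshold).astype(np.int8)
        np.fill_diagonal(adj, 0)
        nets[cid] = BinaryNetwork(adjacency=adj, rsn_labels=labels)
    return nets
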