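"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written without reference to the package
implementation: distances by boolean matrix powers, betweenness by
exhaustive enumeration of simple shortest paths, Wilcoxon p-values by
enumerating all sign assignments, and a stand-alone single-network
spike-and-slab sampler that follows the documented draw-order contract.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- graphs


def bf_distances(adj: np.ndarray) -> np.ndarray:
    """d(i, j) = smallest k with (A^k)_ij > 0, by boolean matrix powers."""
    p = adj.shape[0]
    d = np.full((p, p), np.inf)
    np.fill_diagonal(d, 0.0)
    reach = np.eye(p, dtype=bool)
    power = np.eye(p, dtype=bool)
    a = adj.astype(bool)
    for k in range(1, p):
        power = power @ a
        newly = power & ~reach
        d[newly] = k
        reach |= newly
        if reach.all():
            break
    return d


def bf_global_efficiency(adj: np.ndarray) -> float:
    d = bf_distances(adj)
    p = adj.shape[0]
    off = ~np.eye(p, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def bf_cpl(adj: np.ndarray) -> float:
    d = bf_distances(adj)
    p = adj.shape[0]
    vals = d[~np.eye(p, dtype=bool)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")  # no reachable pair: CPL undefined
    return float(vals.mean())


def bf_clustering(adj: np.ndarray) -> tuple[np.ndarray, float]:
    p = adj.shape[0]
    c = np.zeros(p)
    for i in range(p):
        nbrs = [j for j in range(p) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            adj[u, v] for u, v in itertools.combinations(nbrs, 2)
        )
        c[i] = 2.0 * links / (k * (k - 1))
    return c, float(c.mean())


def bf_local_efficiency(adj: np.ndarray) -> tuple[np.ndarray, float]:
    p = adj.shape[0]
    vals = np.zeros(p)
    for i in range(p):
        nbrs = [j for j in range(p) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        vals[i] = bf_global_efficiency(sub)
    return vals, float(vals.mean())


def _all_shortest_paths(adj: np.ndarray, s: int, t: int, dist: float) -> list[tuple]:
    """All simple paths from s to t of exactly the shortest length."""
    if not np.isfinite(dist):
        return []
    paths = []

    def extend(path):
        last = path[-1]
        if len(path) - 1 == dist:
            if last == t:
                paths.append(tuple(path))
            return
        for nxt in np.flatnonzero(adj[last]):
            if nxt not in path:
                extend(path + [int(nxt)])

    extend([s])
    return paths


def bf_betweenness(adj: np.ndarray, normalized: bool = True) -> np.ndarray:
    p = adj.shape[0]
    d = bf_distances(adj)
    bc = np.zeros(p)
    for s, t in itertools.combinations(range(p), 2):
        paths = _all_shortest_paths(adj, s, t, d[s, t])
        if not paths:
            continue
        for v in range(p):
            if v in (s, t):
                continue
            through = sum(1 for path in paths if v in path)
            bc[v] += through / len(paths)
    if normalized and p > 2:
        bc /= (p - 1) * (p - 2) / 2.0
    return bc


# ---------------------------------------------------------- wilcoxon


def bf_wilcoxon_two_sided_p(diffs: np.ndarray) -> float:
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_le = (ws <= w_obs).mean()
    p_ge = (ws >= w_obs).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


# ------------------------------------------- single-network sampler

def oracle_single_network_mcmc(
    scatter: np.ndarray,
    n_rows: int,
    *,
    v0: float,
    v1: float,
    lambda_diag: float,
    theta_prior_mean: float,
    theta_prior_sd: float,
    n_iter: int,
    burn_in: int,
    seed: int,
    pg_terms: int = 200,
):
    """Stand-alone K=1 spike-and-slab GGM sampler (reduction oracle).

    Follows the documented draw-order contract of the joint sampler: per
    iteration, for each column, p-1 standard normals then one gamma; then
    uniforms (pairs, 1), standard exponentials (pairs, 1, pg_terms),
    normals (pairs,), normals (pairs, 1).  With K = 1 the differential
    effects are identically zero, so the model reduces to a single-network
    spike-and-slab GGM with a logit-normal prior on edge probabilities.
    """
    p = scatter.shape[0]
    rows, cols = np.triu_indices(p, 1)
    P = len(rows)
    rng = np.random.default_rng(seed)
    var = np.diag(scatter) / n_rows
    om = np.diag(1.0 / (var + 1e-6))
    z = np.zeros(P, dtype=int)
    theta = np.full(P, theta_prior_mean)
    kept = []

    def pair_index(i, j):
        lo, hi = min(i, j), max(i, j)
        return np.flatnonzero((rows == lo) & (cols == hi))[0]

    for it in range(1, n_iter + 1):
        for j in range(p):
            idx = [i for i in range(p) if i != j]
            om11 = om[np.ix_(idx, idx)]
            om11_inv = np.linalg.inv(om11)
            s12 = scatter[idx, j]
            sjj = scatter[j, j]
            vvec = np.array(
                [v1 if z[pair_index(i, j)] else v0 for i in idx]
            )
            cinv = (sjj + lambda_diag) * om11_inv + np.diag(1.0 / vvec**2)
            L = np.linalg.cholesky(cinv)
            u = rng.standard_normal(p - 1)
            beta = -np.linalg.solve(cinv, s12) + np.linalg.solve(L.T, u)
            gamma = rng.gamma(n_rows / 2.0 + 1.0, 2.0 / (sjj + lambda_diag))
            for pos, i in enumerate(idx):
                om[i, j] = om[j, i] = beta[pos]
            om[j, j] = gamma + beta @ om11_inv @ beta
        # link sweep (K = 1, delta = 0)
        w = om[rows, cols][:, None]
        psi = np.clip(theta[:, None], -30.0, 30.0)
        log_odds = (
            psi
            + (-0.5 * (w / v1) ** 2 - math.log(v1))
            - (-0.5 * (w / v0) ** 2 - math.log(v0))
        )
        prob = 0.5 * (1.0 + np.tanh(0.5 * log_odds))
        z = (rng.random((P, 1)) < prob).astype(np.uint8)[:, 0]
        # PG(1, psi) truncated-series draw with analytic tail mean
        ks = np.arange(1, pg_terms + 1) - 0.5
        denom = ks**2 + (psi[..., None] / (2 * np.pi)) ** 2
        g = rng.standard_exponential(psi.shape + (pg_terms,))
        pg = (g / denom).sum(axis=-1) / (2 * np.pi**2)
        a = np.abs(psi) / (2 * np.pi)
        tail = np.where(
            a < 1e-12,
            1.0 / pg_terms,
            (np.pi / 2 - np.arctan(pg_terms / np.where(a < 1e-12, 1.0, a)))
            / np.where(a < 1e-12, 1.0, a),
        )
        pg = pg + tail / (2 * np.pi**2)
        kap = z.astype(float)[:, None] - 0.5
        prec = pg.sum(axis=1) + 1.0 / theta_prior_sd**2
        mean = (
            (kap - pg * 0.0).sum(axis=1) + theta_prior_mean / theta_prior_sd**2
        ) / prec
        theta = mean + rng.standard_normal(P) / np.sqrt(prec)
        rng.standard_normal((P, 1))  # delta slot in the draw-order contract
        if it > burn_in:
            kept.append(z.copy())
    return np.mean(kept, axis=0), rows, cols
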