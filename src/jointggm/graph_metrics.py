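"""Graph-theoretic metrics on binary brain networks.

All metrics operate on symmetric 0/1 adjacency matrices with node -> RSN
labels, at whole-network, RSN-subnetwork, and node level, plus metric
posteriors evaluated over sampled MCMC structures.  Shortest paths are hop
counts; disconnected pairs contribute 0 to efficiency and are dropped from
characteristic path length.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_sp


@dataclasses.dataclass
class BinaryNetwork:
    """Symmetric 0/1 adjacency with zero diagonal and per-node RSN labels."""

    adjacency: np.ndarray
    rsn_labels: list[str]
    node_ids: list[int] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        if len(self.rsn_labels) != a.shape[0]:
            raise ValueError("rsn_labels length must equal matrix order")
        self.adjacency = a.astype(np.int8)
        if self.node_ids is None:
            self.node_ids = list(range(a.shape[0]))

    @property
    def node_count(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        return g


@dataclasses.dataclass
class MetricPosterior:
    """One value of a named global metric per retained MCMC iteration."""

    metric_name: str
    condition_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("metric posterior contains non-finite values")


def shortest_paths(net: BinaryNetwork) -> np.ndarray:
    """Hop-count distance matrix; unreachable pairs are +inf, diagonal 0."""
    return _csgraph_sp(csr_matrix(net.adjacency), method="D", unweighted=True)


def _efficiency_from_distances(d: np.ndarray) -> float:
    p = d.shape[0]
    if p < 2:
        raise ValueError("need at least 2 nodes")
    off = ~np.eye(p, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def global_efficiency(net: BinaryNetwork) -> float:
    """Mean of 1/d_ij over distinct pairs, with 1/inf = 0; in [0, 1]."""
    return _efficiency_from_distances(shortest_paths(net))


def characteristic_path_length(net: BinaryNetwork) -> float:
    """Mean hop distance over *reachable* distinct pairs only."""
    d = shortest_paths(net)
    off = ~np.eye(net.node_count, dtype=bool)
    finite = d[off][np.isfinite(d[off])]
    if finite.size == 0:
        raise ValueError("no reachable pair; CPL undefined")
    return float(finite.mean())


def clustering_coefficients(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node C_i = 2 t_i / (k_i (k_i - 1)) and the mean (MCC)."""
    a = net.adjacency.astype(float)
    deg = a.sum(axis=0)
    tri = np.diag(a @ a @ a) / 2.0
    denom = deg * (deg - 1) / 2.0
    c = np.zeros(net.node_count)
    ok = denom > 0
    c[ok] = tri[ok] / denom[ok]
    return c, float(c.mean())


def local_efficiency(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per node, global efficiency of the neighbor-induced subgraph."""
    a = net.adjacency
    vals = np.zeros(net.node_count)
    for i in range(net.node_count):
        nbrs = np.flatnonzero(a[i])
        if len(nbrs) < 2:
            continue
        sub = BinaryNetwork(a[np.ix_(nbrs, nbrs)], ["x"] * len(nbrs))
        vals[i] = global_efficiency(sub)
    return vals, float(vals.mean())


def _degree_preserving_null(g: nx.Graph, rewires_per_edge: int, seed) -> nx.Graph:
    h = g.copy()
    nswap = rewires_per_edge * h.number_of_edges()
    try:
        nx.double_edge_swap(h, nswap=nswap, max_tries=nswap * 20, seed=seed)
    except nx.NetworkXException:
        # No swappable edge pair (e.g. complete graph): the degree sequence
        # fixes the graph, so the graph is its own null.
        pass
    return h


def small_worldedness(
    net: BinaryNetwork,
    n_nulls: int = 20,
    rewires_per_edge: int = 10,
    seed: int = 0,
) -> tuple[float, float, float]:
    """sigma = (C/C_rand) / (L/L_rand) against degree-preserving rewirings.

    C is the mean clustering coefficient and L the characteristic path
    length; C_rand and L_rand are means over ``n_nulls`` Maslov-Sneppen
    randomizations with ``rewires_per_edge`` swaps per edge.
    """
    if net.edge_count == 0:
        raise ValueError("small-worldedness needs at least one edge")
    _, c_obs = clustering_coefficients(net)
    l_obs = characteristic_path_length(net)
    g = net.to_networkx()
    rng = np.random.default_rng(seed)
    c_rand = []
    l_rand = []
    for _ in range(n_nulls):
        h = _degree_preserving_null(g, rewires_per_edge, int(rng.integers(2**31)))
        null = BinaryNetwork(
            nx.to_numpy_array(h, nodelist=range(net.node_count)), net.rsn_labels
        )
        _, c = clustering_coefficients(null)
        c_rand.append(c)
        l_rand.append(characteristic_path_length(null))
    c_rand_m = float(np.mean(c_rand))
    l_rand_m = float(np.mean(l_rand))
    if c_rand_m == 0.0:
        raise ValueError("null graphs have zero clustering; sigma undefined")
    sigma = (c_obs / c_rand_m) / (l_obs / l_rand_m)
    return sigma, c_rand_m, l_rand_m


def betweenness(net: BinaryNetwork, normalized: bool = True) -> np.ndarray:
    """Brandes betweenness; normalized form divides by (n-1)(n-2)/2."""
    bc = nx.betweenness_centrality(net.to_networkx(), normalized=normalized)
    return np.array([bc[i] for i in range(net.node_count)], dtype=float)


def participation_coefficient(net: BinaryNetwork) -> np.ndarray:
    """P_i = 1 - sum_s (k_is / k_i)^2 over modules s; 0 for isolated nodes.

    Nodes labeled "unknown" still count as a module for their neighbors;
    exclude them from cohort averages with :func:`labeled_node_mask`.
    """
    labels = np.asarray(net.rsn_labels)
    a = net.adjacency
    deg = a.sum(axis=0).astype(float)
    p_i = np.zeros(net.node_count)
    modules = np.unique(labels)
    k_is = np.zeros((net.node_count, len(modules)))
    for s, mod in enumerate(modules):
        k_is[:, s] = a[:, labels == mod].sum(axis=1)
    ok = deg > 0
    p_i[ok] = 1.0 - ((k_is[ok] / deg[ok, None]) ** 2).sum(axis=1)
    return p_i


def labeled_node_mask(net: BinaryNetwork) -> np.ndarray:
    """True for nodes assigned to a named RSN (label != 'unknown')."""
    return np.asarray(net.rsn_labels) != "unknown"


def network_summaries(
    net: BinaryNetwork,
    weights: np.ndarray | None = None,
    anticorrelation_modules: tuple[str, str] | None = None,
) -> dict:
    """Edge count, density %, degrees, within-RSN edge %, signed strength.

    Density is 100 * E / (p (p - 1) / 2).  A within-RSN edge joins two
    nodes sharing the same label, that label not being "unknown".  Given a
    symmetric weight matrix (e.g. partial correlations) and two module
    names, the anticorrelation strength is the sum of negative weights on
    edges spanning the two modules.
    """
    p = net.node_count
    e = net.edge_count
    labels = np.asarray(net.rsn_labels)
    rows, cols = np.triu_indices(p, 1)
    present = net.adjacency[rows, cols] == 1
    same = (labels[rows] == labels[cols]) & (labels[rows] != "unknown")
    within = int((present & same).sum())
    out = {
        "edge_count": e,
        "density_pct": 100.0 * e / (p * (p - 1) / 2),
        "degree": net.degrees(),
        "within_rsn_pct": (100.0 * within / e) if e else 0.0,
    }
    if anticorrelation_modules is not None:
        if weights is None:
            raise ValueError("anticorrelation strength requires a weight matrix")
        m1, m2 = anticorrelation_modules
        for m in (m1, m2):
            if m not in labels:
                raise ValueError(f"unknown module name: {m}")
        span = ((labels[rows] == m1) & (labels[cols] == m2)) | (
            (labels[rows] == m2) & (labels[cols] == m1)
        )
        w = np.asarray(weights)[rows, cols]
        neg = present & span & (w < 0)
        out["anticorrelation_strength"] = float(w[neg].sum())
    return out


def rsn_subnetwork_metrics(net: BinaryNetwork, metric: str = "ge") -> dict[str, float]:
    """GE or CPL on the induced subgraph of each labeled RSN.

    An RSN failing the metric's preconditions (fewer than 2 nodes for GE,
    no reachable pair for CPL) is reported as NaN rather than fabricated;
    very small RSNs yield unstable values.
    """
    if metric not in ("ge", "cpl"):
        raise ValueError("metric must be 'ge' or 'cpl'")
    labels = np.asarray(net.rsn_labels)
    out: dict[str, float] = {}
    for mod in dict.fromkeys(net.rsn_labels):
        if mod == "unknown":
            continue
        idx = np.flatnonzero(labels == mod)
        if len(idx) < 2:
            out[mod] = float("nan")
            continue
        sub = BinaryNetwork(
            net.adjacency[np.ix_(idx, idx)], [mod] * len(idx)
        )
        if metric == "ge":
            out[mod] = global_efficiency(sub)
        else:
            try:
                out[mod] = characteristic_path_length(sub)
            except ValueError:
                out[mod] = float("nan")
    return out


_GLOBAL_METRICS = {
    "ge": global_efficiency,
    "cpl": characteristic_path_length,
    "mcc": lambda n: clustering_coefficients(n)[1],
    "le": lambda n: local_efficiency(n)[1],
    "density": lambda n: 100.0 * n.edge_count / (n.node_count * (n.node_count - 1) / 2),
}


def compute_metric(net: BinaryNetwork, metric_name: str, null_config: dict | None = None) -> float:
    """Evaluate one named global metric ('ge', 'cpl', 'mcc', 'le',
    'density', 'sigma')."""
    if metric_name == "sigma":
        cfg = null_config or {}
        return small_worldedness(net, **cfg)[0]
    if metric_name not in _GLOBAL_METRICS:
        raise ValueError(f"unknown metric: {metric_name}")
    return _GLOBAL_METRICS[metric_name](net)


def metric_posterior(
    summary,
    metric_name: str,
    condition_id: str,
    rsn_labels: Iterable[str] | None = None,
    null_config: dict | None = None,
) -> MetricPosterior:
    """Evaluate a global metric on every retained sampled structure.

    This propagates posterior uncertainty about the network into the
    metric: the result is a posterior sample of the metric, not a point
    value on a single estimate.  CPL of an iteration with no reachable
    pair is reported as NaN-free by construction only for connected
    structures; such iterations raise, as they indicate a near-empty model.
    """
    vals = [
        compute_metric(net, metric_name, null_config)
        for net in summary.iteration_networks(condition_id, rsn_labels)
    ]
    return MetricPosterior(metric_name=metric_name, condition_id=condition_id, values=np.asarray(vals))
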