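"""Synthetic ground-truth networks and AR(1)-correlated Gaussian time series.

Emulates the statistical structure of resting-state fMRI summarized to a
node atlas: p nodes partitioned into resting-state-network (RSN) blocks,
sparse precision matrices whose edges concentrate within RSN blocks, a set
of edges shared by every condition (cohort x visit) plus condition-specific
differential edges, temporal autocorrelation within each subject's series,
and several subjects per condition.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

#: Node counts per resting-state network in the 264-node functional atlas
#: used throughout: ten labeled RSNs plus an "unknown" remainder.
ADNI_RSN_SIZES: dict[str, int] = {
    "MedVis": 15,
    "OccPole": 15,
    "LatVis": 19,
    "DMN": 20,
    "Cerebellum": 6,
    "SM": 31,
    "Aud": 29,
    "EC": 39,
    "FPR": 32,
    "FPL": 26,
    "unknown": 32,
}

#: Default condition labels: two cohorts observed at two visits.
DEFAULT_CONDITIONS = ("HC-baseline", "HC-year1", "AD-baseline", "AD-year1")

#: Margin added to the diagonal beyond the absolute off-diagonal row sum;
#: guarantees strict diagonal dominance, hence positive definiteness,
#: without perturbing the planted zero pattern.
PD_MARGIN = 0.1


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclasses.dataclass
class GroundTruthNetworks:
    """Known sparse precision matrices per condition with labeled edges.

    ``shared_edges`` are node pairs present in every condition;
    ``differential_edges[c]`` are pairs unique to condition ``c``.  The
    off-diagonal support of ``precision_matrices[c]`` is exactly
    ``shared_edges | differential_edges[c]``.
    """

    node_count: int
    rsn_labels: list[str]
    condition_ids: list[str]
    precision_matrices: dict[str, np.ndarray]
    shared_edges: set[tuple[int, int]]
    differential_edges: dict[str, set[tuple[int, int]]]

    def edges(self, condition_id: str) -> set[tuple[int, int]]:
        """All true edges (shared plus differential) of one condition."""
        return self.shared_edges | self.differential_edges[condition_id]

    def validate(self) -> None:
        if len(self.rsn_labels) != self.node_count:
            raise ValueError("rsn_labels length must equal node_count")
        for cid in self.condition_ids:
            om = self.precision_matrices[cid]
            if not np.allclose(om, om.T):
                raise ValueError(f"precision for {cid} not symmetric")
            np.linalg.cholesky(om)  # raises if not PD
            support = {
                (i, j)
                for i in range(self.node_count)
                for j in range(i + 1, self.node_count)
                if om[i, j] != 0.0
            }
            if support != self.edges(cid):
                raise ValueError(f"support/edge-set mismatch for {cid}")
            if self.shared_edges & self.differential_edges[cid]:
                raise ValueError("shared and differential edge sets overlap")


@dataclasses.dataclass
class TimeSeriesDataset:
    """Per-subject T x p series with condition labels and provenance."""

    records: list[tuple[str, str, np.ndarray]]
    ar_coefficient: float
    seed: int
    truth: GroundTruthNetworks | None = None

    @property
    def node_count(self) -> int:
        return self.records[0][2].shape[1]

    def condition_ids(self) -> list[str]:
        seen: list[str] = []
        for cid, _, _ in self.records:
            if cid not in seen:
                seen.append(cid)
        return seen

    def subjects(self, condition_id: str) -> list[tuple[str, np.ndarray]]:
        return [(sid, x) for cid, sid, x in self.records if cid == condition_id]

    def validate(self) -> None:
        p = self.node_count
        for cid, sid, x in self.records:
            if x.shape[1] != p:
                raise ValueError(f"subject {sid}: node count mismatch")
            if x.shape[0] < 10:
                raise ValueError(f"subject {sid}: T must be >= 10")
            if self.truth is not None and cid not in self.truth.condition_ids:
                raise ValueError(f"condition {cid} missing from truth")


def _expand_labels(rsn_sizes: Sequence[int], rsn_names: Sequence[str] | None) -> list[str]:
    if rsn_names is None:
        rsn_names = [f"RSN{i + 1}" for i in range(len(rsn_sizes))]
    if len(rsn_names) != len(rsn_sizes):
        raise ConfigurationError("rsn_names and rsn_sizes length mismatch")
    labels: list[str] = []
    for name, size in zip(rsn_names, rsn_sizes):
        labels.extend([name] * size)
    return labels


def generate_ground_truth(
    node_count: int,
    rsn_sizes: Sequence[int],
    within_density: float,
    between_density: float,
    shared_fraction: float,
    condition_ids: Sequence[str] = DEFAULT_CONDITIONS,
    edge_weight_range: tuple[float, float] = (0.2, 0.5),
    seed: int = 0,
    rsn_names: Sequence[str] | None = None,
) -> GroundTruthNetworks:
    """Plant sparse precision matrices with block (RSN) structure.

    Within-RSN node pairs receive candidate edges with probability
    ``within_density`` and between-RSN pairs with probability
    ``between_density``.  A fraction ``shared_fraction`` of the selected
    edges is placed in every condition; the remainder are distributed
    uniformly among single conditions.  Edge weights have magnitude drawn
    uniformly from ``edge_weight_range`` with a random (Rademacher) sign; a
    shared edge keeps one weight across all conditions.  Positive
    definiteness is enforced by diagonal dominance: each diagonal entry is
    the row's absolute off-diagonal sum plus ``PD_MARGIN``.
    """
    if node_count <= 0:
        raise ConfigurationError("node_count must be positive")
    if sum(rsn_sizes) != node_count:
        raise ConfigurationError(
            f"rsn_sizes sum to {sum(rsn_sizes)}, expected node_count={node_count}"
        )
    if any(s <= 0 for s in rsn_sizes):
        raise ConfigurationError("rsn_sizes must be positive")
    for d, name in ((within_density, "within_density"), (between_density, "between_density")):
        if not 0.0 <= d <= 1.0:
            raise ConfigurationError(f"{name} must lie in [0, 1]")
    if not 0.0 <= shared_fraction <= 1.0:
        raise ConfigurationError("shared_fraction must lie in [0, 1]")
    lo, hi = edge_weight_range
    if not 0 < lo <= hi:
        raise ConfigurationError("edge_weight_range must be positive with lo <= hi")
    condition_ids = list(condition_ids)
    if not condition_ids:
        raise ConfigurationError("need at least one condition")

    rng = np.random.default_rng(seed)
    labels = _expand_labels(rsn_sizes, rsn_names)

    # Candidate edge selection by block membership.
    selected: list[tuple[int, int]] = []
    for i in range(node_count):
        for j in range(i + 1, node_count):
            dens = within_density if labels[i] == labels[j] else between_density
            if rng.random() < dens:
                selected.append((i, j))

    order = rng.permutation(len(selected))
    n_shared = int(round(shared_fraction * len(selected)))
    shared = {selected[i] for i in order[:n_shared]}
    differential: dict[str, set[tuple[int, int]]] = {c: set() for c in condition_ids}
    for i in order[n_shared:]:
        cid = condition_ids[rng.integers(len(condition_ids))]
        differential[cid].add(selected[i])

    # One weight per selected edge; shared edges reuse it in every condition.
    weights = {
        e: rng.uniform(lo, hi) * (1.0 if rng.random() < 0.5 else -1.0) for e in selected
    }

    precisions: dict[str, np.ndarray] = {}
    for cid in condition_ids:
        om = np.zeros((node_count, node_count))
        for (i, j) in shared | differential[cid]:
            om[i, j] = om[j, i] = weights[(i, j)]
        np.fill_diagonal(om, np.abs(om).sum(axis=1) + PD_MARGIN)
        precisions[cid] = om

    truth = GroundTruthNetworks(
        node_count=node_count,
        rsn_labels=labels,
        condition_ids=condition_ids,
        precision_matrices=precisions,
        shared_edges=shared,
        differential_edges=differential,
    )
    truth.validate()
    return truth


def sample_time_series(
    truth: GroundTruthNetworks,
    subjects_per_condition: int,
    T: int,
    ar_coefficient: float = 0.3,
    seed: int = 0,
) -> TimeSeriesDataset:
    """Simulate per-subject series x_t = phi * x_{t-1} + eps_t.

    Innovations are eps_t ~ N(0, Omega_c^{-1}) and x_0 is drawn from the
    stationary law N(0, Omega_c^{-1} / (1 - phi^2)); with a scalar phi the
    stationary partial-correlation pattern equals that of Omega_c, so
    prewhitened data carry the planted conditional-independence graph.
    """
    phi = float(ar_coefficient)
    if not abs(phi) < 1.0:
        raise ConfigurationError("|ar_coefficient| must be < 1")
    if T < 10:
        raise ConfigurationError("T must be >= 10")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str, np.ndarray]] = []
    for cid in truth.condition_ids:
        om = truth.precision_matrices[cid]
        cov = np.linalg.inv(om)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise RuntimeError(f"singular precision for {cid}") from exc
        for s in range(subjects_per_condition):
            eps = rng.standard_normal((T, truth.node_count)) @ chol.T
            x = np.empty_like(eps)
            x[0] = eps[0] / np.sqrt(1.0 - phi**2)
            for t in range(1, T):
                x[t] = phi * x[t - 1] + eps[t]
            records.append((cid, f"{cid}_s{s:02d}", x))
    ds = TimeSeriesDataset(
        records=records, ar_coefficient=phi, seed=seed, truth=truth
    )
    ds.validate()
    return ds
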