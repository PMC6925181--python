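"""Shared fixtures: small canonical graphs and the recovery experiment.

The recovery experiment (4 conditions, p = 20 in two RSN blocks, T = 200,
10 subjects per condition, 3000 MCMC iterations) is expensive, so it is
computed once per session and shared by every test that needs a fitted
posterior with known ground truth.
"""

from __future__ import annotations

import numpy as np
import pytest

from jointggm import (
    JointGGMConfig,
    call_edges,
    generate_ground_truth,
    run_mcmc,
    sample_time_series,
)
from jointggm.graph_metrics import BinaryNetwork
from jointggm.preprocess import prepare_condition

RECOVERY_SEED = 20260923


def path_graph(n: int) -> BinaryNetwork:
    a = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return BinaryNetwork(a, ["x"] * n)


def star_graph(n_leaves: int) -> BinaryNetwork:
    n = n_leaves + 1
    a = np.zeros((n, n), dtype=int)
    a[0, 1:] = a[1:, 0] = 1
    return BinaryNetwork(a, ["x"] * n)


def complete_graph(n: int) -> BinaryNetwork:
    a = np.ones((n, n), dtype=int) - np.eye(n, dtype=int)
    return BinaryNetwork(a, ["x"] * n)


def random_network(p: int, density: float, rng: np.random.Generator) -> BinaryNetwork:
    a = np.zeros((p, p), dtype=int)
    rows, cols = np.triu_indices(p, 1)
    on = rng.random(len(rows)) < density
    a[rows[on], cols[on]] = 1
    a = a + a.T
    return BinaryNetwork(a, ["x"] * p)


@pytest.fixture(scope="session")
def recovery_design():
    """Ground truth + dataset for the 4-condition recovery experiment."""
    truth = generate_ground_truth(
        node_count=20,
        rsn_sizes=[10, 10],
        within_density=0.4,
        between_density=0.02,
        shared_fraction=0.7,
        seed=RECOVERY_SEED,
    )
    dataset = sample_time_series(
        truth, subjects_per_condition=10, T=200, ar_coefficient=0.3,
        seed=RECOVERY_SEED + 1,
    )
    cond_data = [prepare_condition(dataset, c) for c in truth.condition_ids]
    return truth, dataset, cond_data


@pytest.fixture(scope="session")
def recovery_fit(recovery_design):
    """3000-iteration joint fit of the recovery design."""
    truth, _, cond_data = recovery_design
    config = JointGGMConfig(n_iter=3000, burn_in=1000, seed=RECOVERY_SEED + 2)
    summary = run_mcmc(cond_data, config)
    nets = call_edges(summary, rsn_labels=truth.rsn_labels)
    return truth, summary, nets
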