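"""Graph-metric worked examples, brute-force equivalence, and invariances."""

import numpy as np
import networkx as nx
import pytest
from _oracles import (
    bf_betweenness,
    bf_clustering,
    bf_cpl,
    bf_global_efficiency,
    bf_local_efficiency,
)
from conftest import complete_graph, path_graph, random_network, star_graph

from jointggm.graph_metrics import (
    BinaryNetwork,
    betweenness,
    characteristic_path_length,
    clustering_coefficients,
    compute_metric,
    global_efficiency,
    local_efficiency,
    metric_posterior,
    network_summaries,
    participation_coefficient,
    rsn_subnetwork_metrics,
    shortest_paths,
    small_worldedness,
)


def k4_minus_edge() -> BinaryNetwork:
    a = np.ones((4, 4), dtype=int) - np.eye(4, dtype=int)
    a[0, 1] = a[1, 0] = 0
    return BinaryNetwork(a, ["x"] * 4)


class TestValidation:
    def test_asymmetric_rejected(self):
        a = np.zeros((3, 3), dtype=int)
        a[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            BinaryNetwork(a, ["x"] * 3)

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            BinaryNetwork(np.eye(3, dtype=int), ["x"] * 3)

    def test_label_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="label"):
            BinaryNetwork(np.zeros((3, 3), dtype=int), ["x"] * 2)


class TestWorkedExamples:
    def test_shortest_paths_path_graph(self):
        d = shortest_paths(path_graph(3))
        assert d[0, 2] == 2 and d[0, 1] == 1

    def test_disconnected_distances_infinite(self):
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = 1
        d = shortest_paths(BinaryNetwork(a, ["x"] * 4))
        assert np.isinf(d[0, 2])

    def test_global_efficiency(self):
        assert global_efficiency(complete_graph(5)) == pytest.approx(1.0)
        assert global_efficiency(path_graph(3)) == pytest.approx(5 / 6)
        empty = BinaryNetwork(np.zeros((4, 4), dtype=int), ["x"] * 4)
        assert global_efficiency(empty) == 0.0

    def test_characteristic_path_length(self):
        assert characteristic_path_length(complete_graph(4)) == pytest.approx(1.0)
        assert characteristic_path_length(path_graph(3)) == pytest.approx(4 / 3)
        assert characteristic_path_length(star_graph(3)) == pytest.approx(1.5)
        empty = BinaryNetwork(np.zeros((3, 3), dtype=int), ["x"] * 3)
        with pytest.raises(ValueError):
            characteristic_path_length(empty)

    def test_clustering(self):
        assert clustering_coefficients(complete_graph(3))[1] == pytest.approx(1.0)
        assert clustering_coefficients(path_graph(3))[1] == 0.0
        assert clustering_coefficients(k4_minus_edge())[1] == pytest.approx(5 / 6)

    def test_local_efficiency(self):
        assert local_efficiency(complete_graph(5))[1] == pytest.approx(1.0)
        vals, mean = local_efficiency(k4_minus_edge())
        assert mean == pytest.approx(11 / 12)
        assert local_efficiency(path_graph(2))[1] == 0.0  # degree-1 nodes

    def test_betweenness(self):
        b = betweenness(star_graph(3))
        assert b[0] == pytest.approx(1.0)
        assert np.allclose(b[1:], 0.0)
        assert betweenness(path_graph(3))[1] == pytest.approx(1.0)

    def test_participation_coefficient(self):
        # all edges within own module
        net = BinaryNetwork(
            complete_graph(4).adjacency, ["A"] * 4
        )
        assert np.allclose(participation_coefficient(net), 0.0)
        # degree 4 split evenly across two modules -> 1 - 2 * 0.25 = 0.5
        a = np.zeros((5, 5), dtype=int)
        a[0, 1:] = a[1:, 0] = 1
        net = BinaryNetwork(a, ["A", "A", "A", "B", "B"])
        assert participation_coefficient(net)[0] == pytest.approx(0.5)
        # isolated node -> 0 by convention
        iso = BinaryNetwork(np.zeros((3, 3), dtype=int), ["A", "B", "A"])
        assert np.allclose(participation_coefficient(iso), 0.0)


class TestBruteForceEquivalence:
    def test_metrics_match_independent_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            p = int(rng.integers(4, 13))
            net = random_network(p, float(rng.uniform(0.15, 0.6)), rng)
            a = net.adjacency
            assert global_efficiency(net) == pytest.approx(bf_global_efficiency(a))
            try:
                cpl = characteristic_path_length(net)
                assert cpl == pytest.approx(bf_cpl(a))
            except ValueError:
                assert not np.isfinite(bf_cpl(a))
            cv, cm = clustering_coefficients(net)
            bcv, bcm = bf_clustering(a)
            assert np.allclose(cv, bcv) and cm == pytest.approx(bcm)
            lv, lm = local_efficiency(net)
            blv, blm = bf_local_efficiency(a)
            assert np.allclose(lv, blv) and lm == pytest.approx(blm)
            assert np.allclose(betweenness(net), bf_betweenness(a), atol=1e-10)


class TestInvariances:
    def test_adding_edges_raises_ge_never_cpl(self):
        # On a connected graph, adding an edge can only shorten paths, so
        # GE is non-decreasing and CPL non-increasing along the chain.
        # (With the reachable-pairs CPL convention this needs
        # connectedness: joining two components adds long new pairs.)
        rng = np.random.default_rng(11)
        for _ in range(5):
            p = 10
            net = random_network(p, 0.25, rng)
            a0 = net.adjacency.copy()
            for i in range(p - 1):  # spanning path keeps it connected
                a0[i, i + 1] = a0[i + 1, i] = 1
            net = BinaryNetwork(a0, net.rsn_labels)
            ge = global_efficiency(net)
            cpl = characteristic_path_length(net)
            a = net.adjacency.copy()
            off = [(i, j) for i in range(p) for j in range(i + 1, p) if not a[i, j]]
            rng.shuffle(off)
            for i, j in off[:10]:
                a[i, j] = a[j, i] = 1
                bigger = BinaryNetwork(a.copy(), net.rsn_labels)
                ge2 = global_efficiency(bigger)
                cpl2 = characteristic_path_length(bigger)
                assert ge2 >= ge - 1e-12
                assert cpl2 <= cpl + 1e-12
                ge, cpl = ge2, cpl2

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(13)
        net = random_network(9, 0.4, rng)
        perm = rng.permutation(9)
        permuted = BinaryNetwork(
            net.adjacency[np.ix_(perm, perm)], [net.rsn_labels[i] for i in perm]
        )
        assert global_efficiency(net) == pytest.approx(global_efficiency(permuted))
        assert clustering_coefficients(net)[1] == pytest.approx(
            clustering_coefficients(permuted)[1]
        )
        assert np.allclose(
            np.sort(betweenness(net)), np.sort(betweenness(permuted))
        )


class TestSmallWorld:
    def test_complete_graph_sigma_one(self):
        sigma, _, _ = small_worldedness(complete_graph(8), n_nulls=3, seed=0)
        assert sigma == pytest.approx(1.0)

    def test_ring_lattice_rewired_is_small_world(self):
        g = nx.watts_strogatz_graph(100, 6, 0.1, seed=5)
        net = BinaryNetwork(nx.to_numpy_array(g, dtype=int), ["x"] * 100)
        sigma, _, _ = small_worldedness(net, n_nulls=20, seed=1)
        assert sigma > 1.5

    def test_random_graph_is_own_null(self):
        g = nx.gnp_random_graph(100, 0.1, seed=7)
        net = BinaryNetwork(nx.to_numpy_array(g, dtype=int), ["x"] * 100)
        sigma, _, _ = small_worldedness(net, n_nulls=20, seed=2)
        assert abs(sigma - 1.0) < 0.3

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            small_worldedness(BinaryNetwork(np.zeros((4, 4), dtype=int), ["x"] * 4))


class TestSummariesAndRSN:
    def test_density_and_within_rsn(self):
        out = network_summaries(complete_graph(4))
        assert out["density_pct"] == pytest.approx(100.0)
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = 1  # within A
        a[2, 3] = a[3, 2] = 1  # within unknown: not counted
        net = BinaryNetwork(a, ["A", "A", "unknown", "unknown"])
        out = network_summaries(net)
        assert out["edge_count"] == 2
        assert out["within_rsn_pct"] == pytest.approx(50.0)

    def test_anticorrelation_strength(self):
        a = np.zeros((4, 4), dtype=int)
        a[0, 2] = a[2, 0] = 1
        a[1, 3] = a[3, 1] = 1
        net = BinaryNetwork(a, ["DMN", "DMN", "DAN", "DAN"])
        w = np.zeros((4, 4))
        w[0, 2] = w[2, 0] = -0.3
        w[1, 3] = w[3, 1] = 0.2
        out = network_summaries(net, weights=w, anticorrelation_modules=("DMN", "DAN"))
        assert out["anticorrelation_strength"] == pytest.approx(-0.3)
        w2 = np.abs(w)  # all positive -> zero anticorrelation
        out2 = network_summaries(net, weights=w2, anticorrelation_modules=("DMN", "DAN"))
        assert out2["anticorrelation_strength"] == 0.0
        with pytest.raises(ValueError, match="unknown module"):
            network_summaries(net, weights=w, anticorrelation_modules=("DMN", "XXX"))

    def test_rsn_submetrics(self):
        a = np.zeros((6, 6), dtype=int)
        # RSN A: triangle (clique); RSN B: 3-node path
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (4, 5)]:
            a[i, j] = a[j, i] = 1
        net = BinaryNetwork(a, ["A"] * 3 + ["B"] * 3)
        assert rsn_subnetwork_metrics(net, "ge") == pytest.approx({"A": 1.0, "B": 5 / 6})
        # RSN with no internal edges -> CPL flagged missing
        empty = BinaryNetwork(np.zeros((4, 4), dtype=int), ["A"] * 2 + ["B"] * 2)
        assert np.isnan(rsn_subnetwork_metrics(empty, "cpl")["A"])


class TestMetricPosterior:
    def test_constant_networks_give_constant_posterior(self, recovery_fit):
        truth, summary, _ = recovery_fit
        import dataclasses

        frozen = dataclasses.replace(
            summary,
            z_draws=np.repeat(summary.z_draws[:1], 20, axis=0),
            partial_draws=summary.partial_draws[:20],
        )
        post = metric_posterior(frozen, "ge", truth.condition_ids[0])
        assert np.ptp(post.values) == 0.0

    def test_density_posterior_consistent_with_edge_counts(self, recovery_fit):
        truth, summary, _ = recovery_fit
        cid = truth.condition_ids[1]
        import dataclasses

        small = dataclasses.replace(
            summary, z_draws=summary.z_draws[:25], partial_draws=summary.partial_draws[:25]
        )
        post = metric_posterior(small, "density", cid)
        p = truth.node_count
        pairs = p * (p - 1) / 2
        counts = small.z_draws[:, :, truth.condition_ids.index(cid)].sum(axis=1)
        assert np.allclose(post.values, 100.0 * counts / pairs)

    def test_ge_posterior_mean_near_truth(self, recovery_fit):
        truth, summary, _ = recovery_fit
        import dataclasses

        cid = truth.condition_ids[0]
        rows, cols = np.triu_indices(truth.node_count, 1)
        true_adj = np.zeros((truth.node_count,) * 2, dtype=int)
        for i, j in truth.edges(cid):
            true_adj[i, j] = true_adj[j, i] = 1
        true_ge = global_efficiency(BinaryNetwork(true_adj, truth.rsn_labels))
        thin = dataclasses.replace(
            summary, z_draws=summary.z_draws[::10], partial_draws=summary.partial_draws[::10]
        )
        post = metric_posterior(thin, "ge", cid)
        assert abs(post.values.mean() - true_ge) < 0.05

    def test_unknown_metric_rejected(self, recovery_fit):
        _, summary, _ = recovery_fit
        with pytest.raises(ValueError, match="unknown metric"):
            compute_metric(
                BinaryNetwork(np.zeros((3, 3), dtype=int), ["x"] * 3), "nope"
            )
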