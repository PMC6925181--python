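"""Joint sampler contracts: PD preservation, reduction oracle, recovery."""

import numpy as np
import pytest
from _oracles import oracle_single_network_mcmc

from jointggm import JointGGMConfig, call_edges, initialize_state, run_mcmc
from jointggm._polya_gamma import pg_draw, pg_mean
from jointggm.joint_network import (
    partial_correlation,
    update_link_and_indicators,
    update_precision_column,
)
from jointggm.preprocess import standardize_and_stack


def _white_condition(p, n, seed, cid="c"):
    rng = np.random.default_rng(seed)
    return standardize_and_stack([rng.standard_normal((n, p))], condition_id=cid)


class TestPolyaGamma:
    @pytest.mark.parametrize("c", [0.0, 0.7, 2.5])
    def test_mean_matches_closed_form(self, c):
        rng = np.random.default_rng(42)
        draws = pg_draw(np.full(20_000, c), rng)
        assert abs(draws.mean() - pg_mean(c)) < 0.003

    def test_variance_at_zero_tilt(self):
        rng = np.random.default_rng(43)
        draws = pg_draw(np.zeros(40_000), rng)
        assert abs(draws.var() - 1.0 / 24.0) < 0.002


class TestPartialCorrelation:
    def test_identity_gives_zero_offdiagonals(self):
        assert np.allclose(partial_correlation(np.eye(4)), np.eye(4))

    def test_two_by_two_sign_flip(self):
        rho = partial_correlation(np.array([[1.0, -0.5], [-0.5, 1.0]]))
        assert rho[0, 1] == pytest.approx(0.5)

    def test_entries_bounded_by_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.standard_normal((6, 6))
            om = a @ a.T + 6 * np.eye(6)
            rho = partial_correlation(om)
            assert np.max(np.abs(rho)) <= 1.0 + 1e-12

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            partial_correlation(np.array([[1.0, 0.0], [0.0, -1.0]]))


class TestConfigAndInit:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            JointGGMConfig(v0=0.5, v1=0.5)
        with pytest.raises(ValueError):
            JointGGMConfig(n_iter=10, burn_in=10)
        with pytest.raises(ValueError):
            JointGGMConfig(edge_call_threshold=1.0)

    def test_initial_state_is_pd_with_centered_delta(self):
        conds = [_white_condition(5, 100, s, f"c{s}") for s in range(2)]
        state = initialize_state(conds, JointGGMConfig())
        for om in state.omegas:
            np.linalg.cholesky(om)
        assert state.delta.shape == (10, 2)
        assert np.allclose(state.delta.sum(axis=1), 0.0)

    def test_empty_condition_list_rejected(self):
        with pytest.raises(ValueError):
            initialize_state([], JointGGMConfig())

    def test_mismatched_node_counts_rejected(self):
        with pytest.raises(ValueError):
            initialize_state(
                [_white_condition(4, 50, 0), _white_condition(5, 50, 1)],
                JointGGMConfig(),
            )


class TestPrecisionUpdate:
    def test_update_preserves_pd(self):
        cond = _white_condition(6, 200, 3)
        config = JointGGMConfig()
        state = initialize_state([cond], config)
        rng = np.random.default_rng(0)
        for _ in range(20):
            for j in range(6):
                update_precision_column(state, 0, j, cond, config, rng)
            assert np.linalg.eigvalsh(state.omegas[0]).min() > 0

    def test_independent_data_concentrates_near_zero(self):
        # True precision is the identity: the off-diagonal posterior mean
        # should shrink to ~0 with n = 5000 rows.
        cond = _white_condition(2, 5000, 4)
        config = JointGGMConfig(n_iter=2000, burn_in=500, seed=5)
        summary = run_mcmc([cond], config)
        off = summary.partial_mean["c"][0, 1]
        assert abs(off) < 0.05


class TestLinkUpdate:
    def test_spike_dominates_at_clamped_negative_logit(self):
        cond = _white_condition(4, 100, 6)
        config = JointGGMConfig()
        state = initialize_state([cond], config)
        state.theta[:] = -100.0  # clamps to -30; omega offdiags are 0 at init
        rng = np.random.default_rng(1)
        update_link_and_indicators(state, config, rng)
        assert state.z.sum() == 0

    def test_large_omega_forces_slab(self):
        # |omega| = 3 v1 makes the slab : spike density ratio astronomical
        # for any pi >= 0.1 (theta = logit 0.1).
        cond = _white_condition(3, 100, 7)
        config = JointGGMConfig()
        state = initialize_state([cond], config)
        for om in state.omegas:
            om[0, 1] = om[1, 0] = 3.0 * config.v1
        state.theta[:] = np.log(0.1 / 0.9)
        rng = np.random.default_rng(2)
        update_link_and_indicators(state, config, rng)
        pair01 = 0  # first upper-triangle pair
        assert state.z[pair01, 0] == 1

    def test_delta_rows_centered_after_update(self):
        conds = [_white_condition(4, 100, s, f"c{s}") for s in range(3)]
        config = JointGGMConfig()
        state = initialize_state(conds, config)
        update_link_and_indicators(state, config, np.random.default_rng(3))
        assert np.allclose(state.delta.sum(axis=1), 0.0, atol=1e-12)


class TestRunMCMC:
    def test_fixed_seed_reproduces_bit_identically(self):
        conds = [_white_condition(4, 80, s, f"c{s}") for s in range(2)]
        config = JointGGMConfig(n_iter=50, burn_in=10, seed=9)
        a = run_mcmc(conds, config)
        b = run_mcmc(conds, config)
        assert np.array_equal(a.z_draws, b.z_draws)
        assert np.array_equal(a.partial_draws, b.partial_draws)

    def test_retained_draw_count_and_pd_sweeps(self):
        conds = [_white_condition(4, 80, 11)]
        config = JointGGMConfig(n_iter=40, burn_in=10, thin=3, seed=1)
        summary = run_mcmc(conds, config, check_pd=True)
        assert summary.n_kept == 10

    def test_reduces_to_single_network_sampler_when_k1(self):
        # Independently coded K=1 spike-and-slab sampler, same seed, same
        # documented draw order => identical retained indicator draws.
        cond = _white_condition(5, 300, 12)
        config = JointGGMConfig(n_iter=200, burn_in=50, seed=13)
        summary = run_mcmc([cond], config)
        pip_oracle, rows, cols = oracle_single_network_mcmc(
            cond.scatter,
            cond.n_rows,
            v0=config.v0,
            v1=config.v1,
            lambda_diag=config.lambda_diag,
            theta_prior_mean=config.theta_prior_mean,
            theta_prior_sd=config.theta_prior_sd,
            n_iter=config.n_iter,
            burn_in=config.burn_in,
            seed=config.seed,
        )
        assert np.array_equal(summary.pair_rows, rows)
        assert np.array_equal(
            summary.pip["c"][rows, cols], pip_oracle
        )

    def test_null_data_specificity(self):
        # Identity-precision data: called-edge density stays below 2%.
        cond = _white_condition(10, 4000, 14)
        config = JointGGMConfig(n_iter=800, burn_in=300, seed=15)
        summary = run_mcmc([cond], config)
        net = call_edges(summary)["c"]
        density = net.edge_count / (10 * 9 / 2)
        assert density < 0.02

    def test_node_relabeling_invariance(self, recovery_design):
        # Permuting node order and un-permuting the output should leave
        # the posterior inclusion probabilities statistically unchanged.
        truth, dataset, _ = recovery_design
        rng = np.random.default_rng(16)
        p = 6
        mats = [x[:, :p] for _, _, x in dataset.records[:6]]
        perm = rng.permutation(p)
        conds = [standardize_and_stack(mats, condition_id="c")]
        conds_perm = [
            standardize_and_stack([m[:, perm] for m in mats], condition_id="c")
        ]
        config = JointGGMConfig(n_iter=1200, burn_in=400, seed=17)
        pip = run_mcmc(conds, config).pip["c"]
        pip_perm = run_mcmc(conds_perm, config).pip["c"]
        unperm = np.empty_like(pip_perm)
        unperm[np.ix_(perm, perm)] = pip_perm
        off = ~np.eye(p, dtype=bool)
        assert np.abs(pip - unperm)[off].mean() < 0.1

    def test_divergence_guard_trips(self):
        cond = _white_condition(3, 50, 18)
        # A wildly indefinite "scatter" destabilizes the conditionals and
        # must abort with a diagnostic instead of returning garbage.
        cond.scatter = 1e5 * np.array(
            [[1.0, 30.0, 0.0], [30.0, 1.0, 30.0], [0.0, 30.0, 1.0]]
        )
        config = JointGGMConfig(n_iter=200, burn_in=1, seed=19)
        with pytest.raises(RuntimeError):
            run_mcmc([cond], config)


class TestCallEdges:
    def test_threshold_rule_exact(self, recovery_fit):
        truth, summary, nets = recovery_fit
        cid = truth.condition_ids[0]
        pip = summary.pip[cid]
        adj = nets[cid].adjacency
        rows, cols = np.triu_indices(truth.node_count, 1)
        assert np.array_equal(adj[rows, cols], (pip[rows, cols] > 0.5).astype(np.int8))

    def test_invalid_threshold_rejected(self, recovery_fit):
        _, summary, _ = recovery_fit
        with pytest.raises(ValueError):
            call_edges(summary, threshold=1.5)


class TestRecovery:
    def test_posterior_partial_correlations_match_truth_on_true_edges(
        self, recovery_fit
    ):
        truth, summary, _ = recovery_fit
        rs, cs = [], []
        est, tru = [], []
        for cid in truth.condition_ids:
            true_pc = partial_correlation(truth.precision_matrices[cid])
            for (i, j) in truth.edges(cid):
                est.append(summary.partial_mean[cid][i, j])
                tru.append(true_pc[i, j])
        r = np.corrcoef(est, tru)[0, 1]
        assert r > 0.8

    def test_called_network_close_to_truth(self, recovery_fit):
        truth, summary, nets = recovery_fit
        rows, cols = np.triu_indices(truth.node_count, 1)
        for cid in truth.condition_ids:
            want = np.array(
                [(int(i), int(j)) in truth.edges(cid) for i, j in zip(rows, cols)]
            )
            got = nets[cid].adjacency[rows, cols] == 1
            hamming = np.mean(want != got)
            assert hamming < 0.10
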