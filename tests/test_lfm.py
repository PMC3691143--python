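import math

import numpy as np
import pytest

from netprior import (
    BetaSourceParams,
    ConfidenceMatrix,
    DirectedNetwork,
    LFMConfig,
    exact_posterior_enumeration,
    log_posterior,
    propose_param_move,
    propose_structure_move,
    run_lfm,
    source_log_likelihood,
)
from netprior.lfm import count_structure_moves
from conftest import labels


def theta2(a, b=0.5):
    return ConfidenceMatrix(labels(2), np.array([[0.0, a], [b, 0.0]]))


def net2(edge01=0, edge10=0):
    return DirectedNetwork(labels(2), np.array([[0, edge01], [edge10, 0]]))


class TestSourceLogLikelihood:
    def test_flat_beta_gives_zero_for_any_network(self):
        th = theta2(0.9, 0.3)
        for om in (net2(0, 0), net2(1, 0), net2(1, 1)):
            assert source_log_likelihood(th, om, 1.0, 1.0) == pytest.approx(0.0)

    def test_present_cell_beta_alpha_one(self):
        # theta=0.9 on a present edge with alpha=2: density 2*theta
        ll = source_log_likelihood(theta2(0.9), net2(1, 0), 2.0, 1.0)
        # absent cell theta=0.5 contributes log Beta(0.5; 1, 1) = 0
        assert ll == pytest.approx(math.log(2 * 0.9))

    def test_absent_cell_beta_one_beta(self):
        # theta=0.9 on an absent edge with beta=2: density 2*(1-theta)
        ll = source_log_likelihood(theta2(0.5, 0.9), net2(1, 0), 1.0, 2.0)
        assert ll == pytest.approx(math.log(2 * 0.1))

    def test_mirrored_form_matches_direct_beta_density(self):
        from scipy.stats import beta as beta_dist

        th, om, a, b = theta2(0.8, 0.3), net2(1, 0), 3.0, 2.0
        ll = source_log_likelihood(th, om, a, b, form="mirrored")
        expected = beta_dist.logpdf(0.8, a, b) + beta_dist.logpdf(0.3, b, a)
        assert ll == pytest.approx(expected)

    def test_boundary_confidence_rejected(self):
        with pytest.raises(ValueError, match="clip"):
            source_log_likelihood(theta2(1.0), net2(1, 0), 2.0, 2.0)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            source_log_likelihood(theta2(0.5), net2(), -1.0, 2.0)


class TestLogPosterior:
    def test_flat_likelihood_reduces_to_bernoulli_prior(self):
        cfg = LFMConfig(edge_prior_rho=0.2)
        th = theta2(0.9, 0.3)
        params = BetaSourceParams([1.0], [1.0])
        for e01, e10 in [(0, 0), (1, 0), (1, 1)]:
            om = net2(e01, e10)
            e = e01 + e10
            expected = e * math.log(0.2) + (2 - e) * math.log(0.8)
            assert log_posterior(om, [th], params, cfg) == pytest.approx(expected)

    def test_hand_computed_two_node_sum(self):
        cfg = LFMConfig(edge_prior_rho=0.05)
        th = theta2(0.9, 0.2)
        params = BetaSourceParams([3.0], [4.0])
        om = net2(1, 0)
        expected = (
            math.log(3.0) + 2.0 * math.log(0.9)      # present, Beta(3,1)
            + math.log(4.0) + 3.0 * math.log(0.8)    # absent, Beta(1,4)
            + math.log(0.05) + math.log(0.95)
        )
        assert log_posterior(om, [th], params, cfg) == pytest.approx(expected)

    def test_denser_graphs_gain_with_rho(self):
        th = theta2(0.9, 0.3)
        params = BetaSourceParams([2.0], [2.0])
        dense, sparse = net2(1, 1), net2(0, 0)
        gap = {}
        for rho in (0.1, 0.4):
            cfg = LFMConfig(edge_prior_rho=rho)
            gap[rho] = log_posterior(dense, [th], params, cfg) - log_posterior(
                sparse, [th], params, cfg
            )
        assert gap[0.4] > gap[0.1]

    def test_out_of_bounds_parameters_are_minus_infinity(self):
        cfg = LFMConfig(param_bounds=(0.1, 1000.0))
        assert log_posterior(
            net2(), [theta2(0.5)], BetaSourceParams([0.01], [1.0]), cfg
        ) == -math.inf


class TestStructureMoves:
    def test_empty_three_node_graph_has_six_insertions(self):
        adj = np.zeros((3, 3), dtype=int)
        assert count_structure_moves(adj) == 6

    def test_complete_digraph_has_six_deletions(self):
        adj = np.ones((3, 3), dtype=int) - np.eye(3, dtype=int)
        assert count_structure_moves(adj) == 6  # no insertions, no reversals

    def test_reversal_preserves_edge_count(self):
        rng = np.random.default_rng(0)
        net = DirectedNetwork.from_edges(labels(3), [("n0", "n1")])
        for _ in range(50):
            new, _ = propose_structure_move(net, rng)
            assert abs(new.n_edges - net.n_edges) <= 1

    def test_hastings_ratio_is_log_count_ratio(self):
        rng = np.random.default_rng(1)
        net = DirectedNetwork.from_edges(labels(3), [("n0", "n1"), ("n1", "n2")])
        new, log_hr = propose_structure_move(net, rng)
        expected = math.log(count_structure_moves(net.adjacency)) - math.log(
            count_structure_moves(new.adjacency)
        )
        assert log_hr == pytest.approx(expected)


class TestParamMoves:
    def test_vanishing_covariance_is_identity_move(self):
        params = BetaSourceParams([2.0, 3.0], [4.0, 5.0])
        out = propose_param_move(params, 1e-30 * np.eye(4), np.random.default_rng(0))
        np.testing.assert_allclose(out.alpha, params.alpha, rtol=1e-6)
        np.testing.assert_allclose(out.beta, params.beta, rtol=1e-6)

    def test_reproducible_under_seed(self):
        params = BetaSourceParams([2.0], [4.0])
        a = propose_param_move(params, np.eye(2), np.random.default_rng(7))
        b = propose_param_move(params, np.eye(2), np.random.default_rng(7))
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.beta, b.beta)

    def test_non_positive_definite_covariance_falls_back(self):
        params = BetaSourceParams([2.0], [4.0])
        bad = -np.eye(2)
        out = propose_param_move(params, bad, np.random.default_rng(3))
        assert np.isfinite(out.alpha).all() and np.isfinite(out.beta).all()


class TestExactEnumeration:
    def test_flat_likelihood_recovers_rho(self):
        cfg = LFMConfig(edge_prior_rho=0.3)
        probs = exact_posterior_enumeration(
            [theta2(0.9, 0.2)], BetaSourceParams([1.0], [1.0]), cfg
        )
        off = ~np.eye(2, dtype=bool)
        np.testing.assert_allclose(probs[off], 0.3, rtol=1e-9)

    def test_hand_computed_four_graph_sum(self):
        """m=2, K=1: enumerate the 4 graphs by hand and compare cellwise."""
        cfg = LFMConfig(edge_prior_rho=0.1)
        th, params = theta2(0.9, 0.2), BetaSourceParams([3.0], [2.0])
        lp = {}
        for e01 in (0, 1):
            for e10 in (0, 1):
                lp[(e01, e10)] = log_posterior(net2(e01, e10), [th], params, cfg)
        w = {k: math.exp(v) for k, v in lp.items()}
        z = sum(w.values())
        expected01 = (w[(1, 0)] + w[(1, 1)]) / z
        probs = exact_posterior_enumeration([th], params, cfg)
        assert probs[0, 1] == pytest.approx(expected01, rel=1e-9)

    def test_symmetric_confidences_give_symmetric_probabilities(self):
        vals = np.array([[0.0, 0.7, 0.2], [0.7, 0.0, 0.4], [0.2, 0.4, 0.0]])
        th = ConfidenceMatrix(labels(3), vals)
        probs = exact_posterior_enumeration(
            [th], BetaSourceParams([4.0], [4.0]), LFMConfig()
        )
        np.testing.assert_allclose(probs, probs.T, rtol=1e-9)

    def test_large_m_rejected(self):
        ths = [ConfidenceMatrix(labels(5), np.full((5, 5), 0.5) - 0.5 * np.eye(5))]
        with pytest.raises(ValueError, match="m <= 4"):
            exact_posterior_enumeration(ths, BetaSourceParams([1.0], [1.0]), LFMConfig())


class TestRunLFM:
    def test_chain_matches_enumeration_small(self, chain_truth):
        truth, params, thetas = chain_truth
        cfg = LFMConfig(
            burn_in=10_000, samples=100_000, rng_seed=2,
            fix_params=True, init_alpha=5.0, init_beta=5.0,
        )
        prior, _ = run_lfm(thetas, cfg)
        exact = exact_posterior_enumeration(thetas, params, cfg)
        off = ~np.eye(3, dtype=bool)
        assert np.abs(prior.values[off] - exact[off]).max() < 0.02

    def test_flat_source_leaves_bernoulli_prior(self):
        th = theta2(0.9, 0.3)
        cfg = LFMConfig(
            burn_in=5_000, samples=50_000, rng_seed=4,
            fix_params=True, edge_prior_rho=0.25,
        )
        prior, _ = run_lfm([th], cfg)
        off = ~np.eye(2, dtype=bool)
        np.testing.assert_allclose(prior.values[off], 0.25, atol=0.02)

    def test_deterministic_under_seed(self, chain_truth):
        _, _, thetas = chain_truth
        cfg = LFMConfig(burn_in=2_000, samples=10_000, rng_seed=9)
        p1, t1 = run_lfm(thetas, cfg)
        p2, t2 = run_lfm(thetas, cfg)
        np.testing.assert_array_equal(p1.values, p2.values)
        np.testing.assert_array_equal(t1.param_samples, t2.param_samples)
        np.testing.assert_array_equal(t1.log_posterior_trace, t2.log_posterior_trace)

    def test_trace_bookkeeping_ranges(self, chain_truth):
        _, _, thetas = chain_truth
        cfg = LFMConfig(burn_in=2_000, samples=10_000, rng_seed=1)
        prior, trace = run_lfm(thetas, cfg)
        assert ((trace.edge_frequency >= 0) & (trace.edge_frequency <= 1)).all()
        for rate in trace.acceptance_rates.values():
            assert np.isnan(rate) or 0 <= rate <= 1
        assert trace.param_samples.shape[1] == 4
        assert np.isfinite(trace.log_posterior_trace).all()

    def test_enumeration_label_permutation_equivariance(self, chain_truth):
        """Permuting node labels permutes posterior edge probabilities identically."""
        _, params, thetas = chain_truth
        cfg = LFMConfig()
        base = exact_posterior_enumeration(thetas, params, cfg)
        perm = [2, 0, 1]
        permuted = [
            ConfidenceMatrix(
                tuple(t.node_labels[p] for p in perm),
                t.values[np.ix_(perm, perm)],
                t.source_name,
            )
            for t in thetas
        ]
        out = exact_posterior_enumeration(permuted, params, cfg)
        np.testing.assert_allclose(out, base[np.ix_(perm, perm)], rtol=1e-9)

    def test_rejects_empty_source_list(self):
        with pytest.raises(ValueError):
            run_lfm([], LFMConfig(burn_in=10, samples=10))
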