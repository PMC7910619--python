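"""Full-conditional samplers and the Gibbs driver."""

import numpy as np
import pytest
from scipy import stats

from ptgen.layouts import NodeLayout, make_grid
from ptgen.mcmc import (
    PosteriorEnsemble,
    chol_with_jitter,
    estimate,
    initial_state,
    run_gibbs,
    sample_H,
    sample_Z,
    sample_beta,
    sample_g,
    sample_r,
)
from ptgen.model import Hyperparams, ModelState, cov_g, cov_h
from ptgen.errors import ParameterError
from ptgen.synthetic import sample_truncated_gp


def one_node_layout(L=1):
    return NodeLayout(np.zeros((1, L)), "rect_grid")


def state_for(layout, beta, g, H, r, assign, N):
    Z = np.zeros((layout.K, N), dtype=np.int8)
    Z[assign, np.arange(N)] = 1
    return ModelState(Z=Z, beta=beta, g=np.asarray(g, float),
                      H=np.asarray(H, float), r=np.asarray(r, float))


class TestSampleZ:
    def test_single_node_forces_assignment(self, rng):
        layout = one_node_layout()
        s = state_for(layout, 1.0, [1.0], [[0.0]], [0.0], [0], 3)
        X = rng.standard_normal((3, 1))
        Z = sample_Z(X, s, rng)
        assert np.array_equal(Z, np.ones((1, 3), dtype=np.int8))

    def test_equidistant_symmetry(self, rng):
        # two nodes mirror-symmetric around the item: 50/50 within 3 sigma
        layout = NodeLayout(np.array([[-0.5], [0.5]]), "rect_grid")
        s = state_for(layout, 2.0, [1.0, 1.0], [[-1.0], [1.0]], [0.0, 0.0], [0], 1)
        X = np.zeros((1, 1))
        draws = np.array([sample_Z(X, s, rng)[0, 0] for _ in range(10_000)])
        p = draws.mean()
        assert abs(p - 0.5) < 3 * 0.5 / np.sqrt(10_000)

    def test_softmax_frequencies_match_enumeration(self, rng):
        # squared distances (0, 1, 4) at beta=2 -> softmax(0, -1, -4)
        layout = NodeLayout(np.array([[0.0], [0.4], [0.8]]), "rect_grid")
        s = state_for(layout, 2.0, np.ones(3), [[0.0], [1.0], [2.0]],
                      np.zeros(3), [0], 1)
        X = np.zeros((1, 1))
        w = np.exp([0.0, -1.0, -4.0])
        p_expected = w / w.sum()
        n = 20_000
        counts = np.zeros(3)
        for _ in range(n):
            counts += sample_Z(X, s, rng)[:, 0]
        freq = counts / n
        sigma = np.sqrt(p_expected * (1 - p_expected) / n)
        assert np.all(np.abs(freq - p_expected) < 4 * sigma)


class TestSampleBeta:
    def test_posterior_mean_perfect_fit(self, rng):
        # SSE = 0, N*D = 4 -> Gamma(2.001, 1e-3), mean about 2001
        layout = one_node_layout()
        s = state_for(layout, 1.0, [1.0], [[0.0, 0.0]], [0.0], [0, 0], 2)
        X = np.zeros((2, 2))
        draws = np.array(
            [sample_beta(X, s, (1e-3, 1e-3), rng) for _ in range(100_000)]
        )
        assert abs(draws.mean() - 2001.0) / 2001.0 < 0.02

    def test_no_data_reproduces_prior_mean(self, rng):
        layout = one_node_layout()
        s = state_for(layout, 1.0, [1.0], [[0.0]], [0.0], [], 0)
        X = np.zeros((0, 1))
        draws = np.array([sample_beta(X, s, (5.0, 2.0), rng) for _ in range(50_000)])
        # prior mean a0/b0 = 2.5, prior sd sqrt(a0)/b0
        se = (np.sqrt(5.0) / 2.0) / np.sqrt(50_000)
        assert abs(draws.mean() - 2.5) < 4 * se

    def test_larger_sse_smaller_beta(self, rng):
        layout = one_node_layout()
        X1 = np.full((4, 1), 1.0)
        X2 = np.full((4, 1), 2.0)  # doubles residuals, quadruples SSE
        s = state_for(layout, 1.0, [1.0], [[0.0]], [0.0], [0, 0, 0, 0], 4)
        m1 = np.mean([sample_beta(X1, s, (1e-3, 1e-3), rng) for _ in range(20_000)])
        m2 = np.mean([sample_beta(X2, s, (1e-3, 1e-3), rng) for _ in range(20_000)])
        assert m1 / m2 == pytest.approx(4.0, rel=0.1)


class TestSampleH:
    def test_prior_limit_without_data(self, rng, hyper):
        # zero items assigned: draws must match the GP prior marginals
        layout = make_grid([2, 2])
        s = state_for(layout, 5.0, np.ones(4), np.zeros((4, 1)), np.zeros(4), [], 0)
        X = np.zeros((0, 1))
        draws = np.stack([sample_H(X, s, layout, hyper, rng)[:, 0] for _ in range(4000)])
        C = cov_h(layout.coords, np.ones(4))
        assert np.allclose(draws.mean(axis=0), 0.0, atol=4 * 1.0 / np.sqrt(4000))
        assert np.allclose(draws.var(axis=0), np.diag(C), rtol=0.15)

    def test_ridge_limit_is_nodewise_average(self, rng, hyper):
        layout = NodeLayout(np.array([[-1.0], [1.0]]), "rect_grid")
        X = np.array([[2.0], [2.2], [-3.0], [-3.4]])
        s = state_for(layout, 1e8, np.ones(2), np.zeros((2, 1)), np.zeros(2),
                      [0, 0, 1, 1], 4)
        draws = np.stack([sample_H(X, s, layout, hyper, rng) for _ in range(200)])
        assert np.allclose(draws.mean(axis=0)[:, 0], [2.1, -3.2], atol=1e-2)

    def test_matches_generic_gaussian_conditioning(self, rng, hyper):
        # brute-force oracle: posterior moments from dense Bayesian linear
        # algebra on a fixed K=2 toy
        layout = NodeLayout(np.array([[-0.5], [0.5]]), "rect_grid")
        g = np.array([2.0, 0.5])
        r = np.array([0.3, -0.2])
        beta = 4.0
        X = np.array([[1.0], [1.4], [-0.8]])
        assign = [0, 0, 1]
        s = state_for(layout, beta, g, np.zeros((2, 1)), r, assign, 3)
        C = cov_h(layout.coords, np.exp(r)) + 1e-6 * np.eye(2)
        counts = np.array([2.0, 1.0])
        A = np.linalg.inv(C) + beta * np.diag(g**2 * counts)
        b = beta * g * np.array([X[0, 0] + X[1, 0], X[2, 0]])
        mean_oracle = np.linalg.solve(A, b)
        cov_oracle = np.linalg.inv(A)
        n = 100_000
        draws = np.stack([sample_H(X, s, layout, hyper, rng)[:, 0] for _ in range(n)])
        se = np.sqrt(np.diag(cov_oracle) / n)
        assert np.all(np.abs(draws.mean(axis=0) - mean_oracle) < 3 * se)
        assert np.allclose(np.cov(draws.T), cov_oracle, rtol=0.05, atol=1e-4)


class TestSampleG:
    def test_always_positive(self, rng, hyper, grid3):
        s = state_for(grid3, 2.0, np.ones(9), rng.standard_normal((9, 2)),
                      np.zeros(9), rng.integers(0, 9, 5), 5)
        X = rng.standard_normal((5, 2))
        for _ in range(50):
            g = sample_g(X, s, grid3, hyper, rng)
            assert np.all(g > 0)
            s.g = g

    def test_prior_reproduction_half_normal(self, rng):
        # far-separated nodes make C_g diagonal, so the truncated-GP
        # marginal is half-normal; with no data the chain must sample it
        hy = Hyperparams(l_g=1e-3)
        layout = NodeLayout(np.array([[-1.0], [1.0]]), "rect_grid")
        s = state_for(layout, 1.0, np.ones(2), np.zeros((2, 1)), np.zeros(2), [], 0)
        X = np.zeros((0, 1))
        chain = []
        for _ in range(4000):
            s.g = sample_g(X, s, layout, hy, rng)
            chain.append(s.g[0])
        chain = np.array(chain[::4])
        ref = np.abs(rng.standard_normal(2000)) * np.sqrt(hy.nu_g)
        assert stats.ks_2samp(chain, ref).pvalue > 0.01

    def test_posterior_concentration(self, rng, hyper):
        # one node, h=1, one item at 2, huge beta: g must sit near 2
        layout = one_node_layout()
        s = state_for(layout, 1e6, [1.0], [[1.0]], [0.0], [0], 1)
        X = np.array([[2.0]])
        chain = []
        for _ in range(500):
            s.g = sample_g(X, s, layout, hyper, rng)
            chain.append(s.g[0])
        assert abs(np.mean(chain[100:]) - 2.0) < 0.01


class TestSampleR:
    def test_degenerate_prior_pins_r_to_zero(self, rng, grid3):
        hy = Hyperparams(nu_r=1e-12)
        s = state_for(grid3, 1.0, np.ones(9), rng.standard_normal((9, 2)),
                      np.zeros(9), rng.integers(0, 9, 4), 4)
        X = rng.standard_normal((4, 2))
        r = sample_r(X, s, grid3, hy, rng)
        assert np.all(np.abs(r) < 1e-4)

    def test_every_sweep_returns_valid_state(self, rng, hyper, grid3):
        s = state_for(grid3, 1.0, np.ones(9), rng.standard_normal((9, 2)),
                      np.zeros(9), rng.integers(0, 9, 4), 4)
        X = rng.standard_normal((4, 2))
        for _ in range(25):
            s.r = sample_r(X, s, grid3, hyper, rng)
            assert np.all(np.isfinite(s.r))


class TestRunGibbsAndEstimate:
    def test_bitwise_reproducibility(self, hyper, grid3, rng):
        X = rng.standard_normal((6, 3))
        a = run_gibbs(X, grid3, hyper, 30, 10, seed=7)
        b = run_gibbs(X, grid3, hyper, 30, 10, seed=7)
        assert a.log_likelihoods == b.log_likelihoods
        assert np.array_equal(a.states[-1].H, b.states[-1].H)

    def test_boundary_single_state(self, hyper, grid3, rng):
        X = rng.standard_normal((5, 2))
        ens = run_gibbs(X, grid3, hyper, 6, 5, seed=1)
        assert len(ens) == 1

    def test_invalid_schedule_rejected(self, hyper, grid3):
        with pytest.raises(ParameterError):
            run_gibbs(np.zeros((3, 2)), grid3, hyper, 5, 5, seed=0)

    def test_estimate_of_identical_states(self, grid3, rng):
        Z = np.zeros((9, 4), dtype=np.int8)
        Z[0, :] = 1
        s = ModelState(Z, 2.0, np.ones(9), rng.standard_normal((9, 2)), np.zeros(9))
        ens = PosteriorEnsemble([s.copy(), s.copy()], [0.0, 0.0], {})
        est = estimate(ens)
        assert est.beta == 2.0
        assert np.array_equal(est.Z, s.Z)
        assert np.allclose(est.H, s.H)

    def test_estimate_averages_fields(self, grid3):
        Z = np.zeros((2, 1), dtype=np.int8)
        Z[0, 0] = 1
        mk = lambda g: ModelState(Z.copy(), 1.0, np.array(g), np.zeros((2, 1)), np.zeros(2))
        ens = PosteriorEnsemble([mk([1.0, 3.0]), mk([3.0, 1.0])], [0.0, 0.0], {})
        assert np.allclose(estimate(ens).g, [2.0, 2.0])

    def test_estimate_empty_rejected(self):
        with pytest.raises(ParameterError):
            estimate(PosteriorEnsemble([], [], {}))

    def test_ensemble_roundtrip(self, tmp_path, hyper, grid3, rng):
        X = rng.standard_normal((5, 2))
        ens = run_gibbs(X, grid3, hyper, 12, 8, seed=3)
        path = tmp_path / "ens.npz"
        ens.save(path)
        back = PosteriorEnsemble.load(path)
        assert back.log_likelihoods == pytest.approx(ens.log_likelihoods)
        assert np.array_equal(back.states[0].Z, ens.states[0].Z)
        assert back.config["n_sweeps"] == 12

    def test_initial_state_is_valid_and_deterministic(self, grid3, rng):
        X = rng.standard_normal((7, 4))
        a = initial_state(X, grid3)
        b = initial_state(X, grid3)
        a.validate()
        assert np.array_equal(a.H, b.H) and np.array_equal(a.Z, b.Z)
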