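"""Kernels, manifold map and complete-data log density."""

import numpy as np
import pytest

from ptgen.errors import ParameterError
from ptgen.model import (
    JITTER,
    FeatureMatrix,
    Hyperparams,
    ModelState,
    cov_g,
    cov_h,
    log_joint,
    manifold_points,
)


class TestCovG:
    def test_diagonal_is_nu(self, hyper, square5):
        C = cov_g(square5.coords, hyper)
        assert np.allclose(np.diag(C), hyper.nu_g)

    def test_characteristic_decay_point(self, hyper):
        # squared distance equal to 2*l_g gives nu_g / e
        U = np.array([[0.0], [np.sqrt(2.0 * hyper.l_g)]])
        C = cov_g(U, hyper)
        assert np.isclose(C[0, 1], hyper.nu_g * np.exp(-1.0))

    def test_long_range_limit(self, hyper):
        U = np.array([[0.0, 0.0], [0.9e3, 0.0]])  # far apart
        assert cov_g(U, hyper)[0, 1] < 1e-12

    def test_l_squared_variant(self):
        hy = Hyperparams(kernel_g_denominator="l_squared")
        U = np.array([[0.0], [1.0]])
        assert np.isclose(cov_g(U, hy)[0, 1], hy.nu_g * np.exp(-1.0 / (2 * hy.l_g**2)))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ParameterError):
            Hyperparams(nu_g=-1.0)
        with pytest.raises(ParameterError):
            Hyperparams(l_g=0.0)


class TestCovH:
    def test_unit_diagonal_for_any_lengthscales(self, rng):
        U = rng.uniform(-1, 1, size=(12, 3))
        l = rng.uniform(0.1, 5.0, size=12)
        assert np.allclose(np.diag(cov_h(U, l)), 1.0)

    def test_constant_l_reduces_to_rbf(self, rng):
        U = rng.uniform(-1, 1, size=(8, 2))
        l = 0.7
        C = cov_h(U, np.full(8, l))
        from scipy.spatial.distance import cdist

        expected = np.exp(-cdist(U, U, "sqeuclidean") / (2 * l**2))
        assert np.allclose(C, expected)

    def test_hand_evaluated_entry(self):
        # L=2, l_i=1, l_j=2, distance 1: prefactor (2*1*2/5)^1, exponent -1/5
        U = np.array([[0.0, 0.0], [1.0, 0.0]])
        C = cov_h(U, np.array([1.0, 2.0]))
        assert np.isclose(C[0, 1], (4.0 / 5.0) * np.exp(-1.0 / 5.0))

    def test_nonpositive_lengthscale_rejected(self):
        with pytest.raises(ParameterError):
            cov_h(np.zeros((2, 2)), np.array([1.0, -1.0]))

    def test_psd_with_jitter_on_random_node_sets(self, rng):
        for _ in range(25):
            K = rng.integers(3, 15)
            L = rng.integers(1, 4)
            U = rng.uniform(-1, 1, size=(K, L))
            l = rng.uniform(0.05, 4.0, size=K)
            C = cov_h(U, l) + JITTER * np.eye(K)
            np.linalg.cholesky(C)  # raises if not PD


class TestManifoldAndLogJoint:
    def test_unit_scale_is_identity(self, rng):
        H = rng.standard_normal((5, 3))
        assert np.array_equal(manifold_points(np.ones(5), H), H)

    def test_elementwise_product(self):
        Y = manifold_points(np.array([2.0, 3.0]), np.eye(2))
        assert np.allclose(Y, [[2.0, 0.0], [0.0, 3.0]])

    def test_standard_normal_at_mean(self):
        state = ModelState(
            Z=np.ones((1, 1), dtype=np.int8),
            beta=1.0,
            g=np.array([1.0]),
            H=np.array([[0.0]]),
            r=np.zeros(1),
        )
        X = np.array([[0.0]])
        assert np.isclose(log_joint(X, state), -0.5 * np.log(2 * np.pi))

    def test_doubling_beta_on_perfect_fit(self, rng):
        K, N, D = 4, 6, 3
        H = rng.standard_normal((K, D))
        g = np.abs(rng.standard_normal(K)) + 0.1
        assign = rng.integers(0, K, N)
        Z = np.zeros((K, N), dtype=np.int8)
        Z[assign, np.arange(N)] = 1
        X = (g[:, None] * H)[assign]  # items exactly on the manifold
        s1 = ModelState(Z, 1.0, g, H, np.zeros(K))
        s2 = ModelState(Z.copy(), 2.0, g.copy(), H.copy(), np.zeros(K))
        assert np.isclose(
            log_joint(X, s2) - log_joint(X, s1), N * D * np.log(2.0) / 2.0
        )

    def test_item_permutation_invariance(self, rng):
        K, N, D = 5, 7, 2
        state = ModelState(
            Z=np.eye(K, N, dtype=np.int8)[:, :N] * 0, beta=1.3,
            g=np.abs(rng.standard_normal(K)) + 0.1,
            H=rng.standard_normal((K, D)), r=np.zeros(K),
        )
        assign = rng.integers(0, K, N)
        Z = np.zeros((K, N), dtype=np.int8)
        Z[assign, np.arange(N)] = 1
        state.Z = Z
        X = rng.standard_normal((N, D))
        perm = rng.permutation(N)
        state_p = ModelState(Z[:, perm], state.beta, state.g, state.H, state.r)
        assert np.isclose(log_joint(X, state), log_joint(X[perm], state_p))

    def test_single_reassignment_decomposition(self, rng):
        # moving one item changes log_joint by beta/2 times the difference
        # of its two squared distances
        K, N, D = 4, 5, 3
        g = np.abs(rng.standard_normal(K)) + 0.5
        H = rng.standard_normal((K, D))
        assign = rng.integers(0, K, N)
        Z = np.zeros((K, N), dtype=np.int8)
        Z[assign, np.arange(N)] = 1
        X = rng.standard_normal((N, D))
        beta = 1.7
        s = ModelState(Z, beta, g, H, np.zeros(K))
        base = log_joint(X, s)
        Y = s.Y
        n, new_k = 2, (assign[2] + 1) % K
        Z2 = Z.copy()
        Z2[:, n] = 0
        Z2[new_k, n] = 1
        s2 = ModelState(Z2, beta, g, H, np.zeros(K))
        expected_delta = (beta / 2.0) * (
            np.sum((X[n] - Y[assign[n]]) ** 2) - np.sum((X[n] - Y[new_k]) ** 2)
        )
        assert np.isclose(log_joint(X, s2) - base, expected_delta)


class TestFeatureMatrix:
    def test_standardization_moments_and_retention(self, rng):
        raw = rng.standard_normal((20, 4)) * 3.0 + 5.0
        fm = FeatureMatrix.standardized(raw, [f"i{i}" for i in range(20)])
        assert np.allclose(fm.X.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(fm.X.var(axis=0), 1.0, atol=1e-9)
        assert np.allclose(fm.column_means, raw.mean(axis=0))
        assert np.allclose(fm.column_sds, raw.std(axis=0))

    def test_missing_values_rejected(self):
        with pytest.raises(ParameterError):
            FeatureMatrix(np.array([[1.0, np.nan]]), ["a"])

    def test_csv_roundtrip(self, tmp_path, rng):
        fm = FeatureMatrix(rng.standard_normal((6, 3)), list("abcdef"))
        path = tmp_path / "fm.csv"
        fm.to_csv(path)
        back = FeatureMatrix.from_csv(path, standardize=False)
        assert back.item_labels == fm.item_labels
        assert np.allclose(back.X, fm.X)


class TestModelStateInvariants:
    def test_column_sum_enforced(self):
        bad = ModelState(
            Z=np.zeros((2, 2), dtype=np.int8), beta=1.0,
            g=np.ones(2), H=np.zeros((2, 1)), r=np.zeros(2),
        )
        with pytest.raises(ParameterError):
            bad.validate()

    def test_positivity_enforced(self):
        Z = np.array([[1, 1]], dtype=np.int8)
        s = ModelState(Z, 1.0, np.array([-0.1]), np.zeros((1, 1)), np.zeros(1))
        with pytest.raises(ParameterError):
            s.validate()
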