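import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.cross_decomposition import PLSRegression

import nitrauv as nv
from nitrauv.kpls import KPLSError


class TestKernelMatrix:
    def test_linear_hand_example(self):
        X = np.array([[1.0, 0.0], [0.0, 2.0]])
        K = nv.kernel_matrix(X, X, nv.KernelSpec("linear"))
        np.testing.assert_array_equal(K, [[1.0, 0.0], [0.0, 4.0]])

    @given(gamma=st.floats(0.01, 10.0))
    def test_rbf_diagonal_is_one(self, gamma):
        X = np.random.default_rng(0).standard_normal((6, 3))
        K = nv.kernel_matrix(X, X, nv.KernelSpec("rbf", gamma))
        np.testing.assert_allclose(np.diag(K), 1.0, atol=1e-12)

    @given(seed=st.integers(0, 100))
    def test_symmetry(self, seed):
        X = np.random.default_rng(seed).standard_normal((5, 4))
        for spec in (nv.KernelSpec("linear"), nv.KernelSpec("rbf", 0.7)):
            K = nv.kernel_matrix(X, X, spec)
            np.testing.assert_allclose(K, K.T, atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(KPLSError):
            nv.kernel_matrix(np.zeros((3, 2)), np.zeros((3, 4)),
                             nv.KernelSpec("linear"))


class TestCentering:
    def test_centered_kernel_has_zero_margins(self):
        K = np.random.default_rng(1).random((8, 8))
        K = K @ K.T
        Kc = nv.center_train_kernel(K)
        np.testing.assert_allclose(Kc.sum(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Kc.sum(axis=1), 0.0, atol=1e-10)

    def test_centering_idempotent(self):
        K = np.random.default_rng(2).random((6, 6))
        K = K @ K.T
        Kc = nv.center_train_kernel(K)
        np.testing.assert_allclose(nv.center_train_kernel(Kc), Kc, atol=1e-10)

    def test_explicit_feature_map_oracle(self):
        # linear-kernel centering == kernel of column-centered X
        rng = np.random.default_rng(3)
        X = rng.standard_normal((10, 4))
        Z = rng.standard_normal((5, 4))
        Xc = X - X.mean(axis=0)
        Zc = Z - X.mean(axis=0)  # test features centered by TRAIN means
        spec = nv.KernelSpec("linear")
        K = nv.kernel_matrix(X, X, spec)
        np.testing.assert_allclose(
            nv.center_train_kernel(K), Xc @ Xc.T, atol=1e-10
        )
        np.testing.assert_allclose(
            nv.center_test_kernel(nv.kernel_matrix(X, Z, spec), K),
            Zc @ Xc.T, atol=1e-10,
        )


class TestFitPredict:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((20, 5))
        y = X @ rng.standard_normal(5) + 2.0
        m = nv.fit_kpls(X, y, nv.KernelSpec("linear"), n_components=5)
        resid = nv.predict_kpls(m, X) - y
        assert np.abs(resid).max() < 1e-8

    def test_two_sample_hand_solution(self):
        # X = [[1], [-1]], y = [1, -1]: one component reproduces y exactly;
        # by hand alpha = [0.5, -0.5] on the centered kernel [[1,-1],[-1,1]]
        X = np.array([[1.0], [-1.0]])
        y = np.array([1.0, -1.0])
        m = nv.fit_kpls(X, y, nv.KernelSpec("linear"), n_components=1)
        np.testing.assert_allclose(m.alpha[:, 0], [0.5, -0.5], atol=1e-12)
        np.testing.assert_allclose(nv.predict_kpls(m, X), y, atol=1e-12)

    @pytest.mark.parametrize("n_components", [1, 2, 3, 4, 5])
    def test_matches_classical_pls(self, n_components):
        rng = np.random.default_rng(10 + n_components)
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        Xt = rng.standard_normal((8, 5))
        m = nv.fit_kpls(X, y, nv.KernelSpec("linear"),
                        n_components=n_components)
        ref = PLSRegression(n_components=n_components, scale=False).fit(
            X, y.reshape(-1, 1)
        )
        np.testing.assert_allclose(
            nv.predict_kpls(m, Xt), ref.predict(Xt).ravel(), atol=1e-6
        )

    def test_duplicated_training_row_reproduces_fitted_value(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((15, 3))
        y = rng.standard_normal(15)
        m = nv.fit_kpls(X, y, nv.KernelSpec("rbf", 0.5), n_components=4)
        fitted = nv.predict_kpls(m, X)
        again = nv.predict_kpls(m, X[[3]])
        assert again[0] == pytest.approx(fitted[3], abs=1e-10)

    def test_score_vectors_orthonormal(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((25, 6))
        y = rng.standard_normal(25)
        m = nv.fit_kpls(X, y, nv.KernelSpec("rbf", 0.3), n_components=6)
        np.testing.assert_allclose(m.T.T @ m.T, np.eye(6), atol=1e-8)

    def test_training_r2_nondecreasing_in_components(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((25, 6))
        y = rng.standard_normal(25)
        r2s = []
        for a in range(1, 8):
            m = nv.fit_kpls(X, y, nv.KernelSpec("rbf", 0.3), n_components=a)
            r2s.append(nv.r_squared(y, nv.predict_kpls(m, X)))
        assert np.all(np.diff(r2s) >= -1e-10)

    def test_constant_inputs_abort_cleanly(self):
        X = np.ones((10, 3))
        y = np.arange(10.0)
        with pytest.raises(KPLSError, match="no further variation|collapsed"):
            nv.fit_kpls(X, y, nv.KernelSpec("linear"), n_components=1)

    def test_invalid_component_count(self):
        X = np.random.default_rng(0).standard_normal((5, 2))
        with pytest.raises(KPLSError):
            nv.fit_kpls(X, np.zeros(5), nv.KernelSpec("linear"),
                        n_components=5)


class TestSelectComponents:
    def test_exact_linear_data_needs_rank_components(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((30, 4))
        y = X @ rng.standard_normal(4)
        a = nv.select_components(X, y, nv.KernelSpec("linear"),
                                 r2_threshold=0.9995, a_max=10)
        assert a <= 4
        m = nv.fit_kpls(X, y, nv.KernelSpec("linear"), n_components=a)
        assert nv.r_squared(y, nv.predict_kpls(m, X)) >= 0.9995

    def test_pure_noise_returns_a_max_with_warning(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        with pytest.warns(UserWarning, match="never reached"):
            a = nv.select_components(X, y, nv.KernelSpec("linear"),
                                     r2_threshold=1.0 - 1e-12, a_max=3)
        assert a == 3

    def test_zero_threshold_selects_one(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((20, 3))
        y = X @ np.array([1.0, 2.0, 3.0]) + rng.standard_normal(20)
        assert nv.select_components(X, y, nv.KernelSpec("linear"),
                                    r2_threshold=0.0, a_max=3) == 1


def test_median_heuristic_positive_and_scale_consistent():
    rng = np.random.default_rng(15)
    X = rng.standard_normal((30, 4))
    g = nv.median_heuristic_gamma(X)
    assert g > 0
    # doubling the data scale quarters gamma
    assert nv.median_heuristic_gamma(2 * X) == pytest.approx(g / 4, rel=1e-9)
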