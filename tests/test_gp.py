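"""Kernel, marginal-likelihood, and posterior-prediction correctness.

Two independent oracles: an explicit Gaussian-conditioning formula written
directly from the joint-normal identities, and (where families coincide)
scikit-learn's GaussianProcessRegressor.
"""

import numpy as np
import pytest

from capsidfit.gp import (
    KERNEL_FAMILIES,
    GPModel,
    KernelSpec,
    kernel_eval,
    kernel_matrix,
    nlml,
    predict,
    train_gp,
)


def make_spec(family, d=3, ls=None):
    ls = np.array([1.0, 0.7, 1.3][:d]) if ls is None else ls
    return KernelSpec(
        family=family,
        signal_variance=2.0,
        lengthscales=np.array([float(np.mean(ls))]) if family == "rq_iso" else ls,
        noise_variance=1e-8,
        alpha=1.5,
        periods=np.array([3.0, 4.0, 5.0][:d]) if family == "gabor_ard" else None,
    )


class TestKernels:
    @pytest.mark.parametrize("family", KERNEL_FAMILIES)
    def test_symmetry_and_diagonal(self, family):
        rng = np.random.default_rng(0)
        X = rng.uniform(-2, 2, (25, 3))
        spec = make_spec(family)
        K = kernel_matrix(spec, X, X)
        assert np.allclose(K, K.T, atol=1e-12)
        if family not in ("neural_network",):
            assert np.allclose(np.diag(K), spec.signal_variance)

    @pytest.mark.parametrize("family", KERNEL_FAMILIES)
    def test_positive_semidefinite_random_sets(self, family):
        rng = np.random.default_rng(42)
        spec = make_spec(family)
        for _ in range(100):
            X = rng.uniform(-3, 3, (12, 3))
            K = kernel_matrix(spec, X, X) + 1e-10 * np.eye(12)
            assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_se_ard_at_zero_distance(self):
        spec = make_spec("se_ard")
        x = np.array([0.3, -0.2, 1.0])
        assert kernel_eval(spec, x, x) == pytest.approx(spec.signal_variance)

    def test_rq_large_alpha_approaches_se(self):
        rng = np.random.default_rng(1)
        ls = np.array([1.0, 0.7, 1.3])
        rq = KernelSpec("rq_ard", 2.0, ls, 1e-8, alpha=1e6)
        se = KernelSpec("se_ard", 2.0, ls, 1e-8)
        for _ in range(10):
            x1, x2 = rng.uniform(-1, 1, (2, 3))
            assert kernel_eval(rq, x1, x2) == pytest.approx(
                kernel_eval(se, x1, x2), rel=1e-4
            )

    @pytest.mark.parametrize("family", ["matern32_ard", "matern52_ard", "se_ard",
                                        "rq_ard", "rq_iso", "gabor_ard"])
    def test_stationary_families_translation_invariant(self, family):
        spec = make_spec(family)
        rng = np.random.default_rng(2)
        x1, x2 = rng.uniform(-1, 1, (2, 3))
        shift = rng.uniform(-5, 5, 3)
        assert kernel_eval(spec, x1, x2) == pytest.approx(
            kernel_eval(spec, x1 + shift, x2 + shift), rel=1e-12
        )

    def test_matches_sklearn_matern_and_rbf(self):
        sklearn_gp = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process.kernels import RBF, Matern

        rng = np.random.default_rng(3)
        X = rng.uniform(-2, 2, (15, 3))
        ls = np.array([1.0, 0.7, 1.3])
        for fam, sk in [
            ("se_ard", RBF(length_scale=ls)),
            ("matern32_ard", Matern(length_scale=ls, nu=1.5)),
            ("matern52_ard", Matern(length_scale=ls, nu=2.5)),
        ]:
            spec = KernelSpec(fam, 1.0, ls, 0.0)
            assert np.allclose(kernel_matrix(spec, X, X), sk(X), atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        spec = make_spec("se_ard")
        with pytest.raises(ValueError):
            kernel_matrix(spec, np.zeros((2, 3)), np.zeros((2, 4)))


class TestNlml:
    def test_one_point_closed_form(self):
        spec = make_spec("se_ard", d=2, ls=np.array([1.0, 1.0]))
        x = np.array([[0.5, -0.5]])
        m = GPModel(spec, x, np.array([3.7]), mean_constant=3.7)
        k = kernel_eval(spec, x[0], x[0]) + spec.noise_variance
        assert nlml(m) == pytest.approx(0.5 * np.log(2 * np.pi * k), rel=1e-9)

    def test_translation_invariance_stationary(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(-1, 1, (20, 3))
        y = rng.standard_normal(20)
        spec = make_spec("matern52_ard")
        a = nlml(GPModel(spec, X, y, float(y.mean())))
        b = nlml(GPModel(spec, X + 7.7, y, float(y.mean())))
        assert a == pytest.approx(b, rel=1e-9)

    def test_huge_noise_approaches_pure_noise_likelihood(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(-1, 1, (15, 2))
        y = rng.standard_normal(15)
        big = 1e8
        spec = KernelSpec("se_ard", 1.0, np.ones(2), big)
        val = nlml(GPModel(spec, X, y, 0.0))
        pure = 0.5 * (y @ y) / big + 0.5 * 15 * np.log(2 * np.pi * big)
        assert val == pytest.approx(pure, rel=1e-4)


class TestPredict:
    def test_interpolates_noiseless_and_reverts_to_prior(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(-1, 1, (10, 2))
        y = np.sin(X[:, 0]) + X[:, 1] ** 2
        spec = KernelSpec("se_ard", 2.0, np.array([0.8, 0.8]), 0.0)
        m = GPModel(spec, X, y, float(y.mean()))
        mu, var = predict(m, X)
        assert np.allclose(mu, y, atol=1e-5)
        assert np.all(var < 1e-6)
        far = np.array([50.0, -50.0])
        mu_f, var_f = predict(m, far)
        assert mu_f == pytest.approx(float(y.mean()), abs=1e-6)
        assert var_f == pytest.approx(2.0, rel=1e-6)

    def test_posterior_variance_below_prior(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(-2, 2, (30, 2))
        y = rng.standard_normal(30)
        spec = KernelSpec("matern32_ard", 1.5, np.array([1.0, 1.0]), 0.0)
        m = GPModel(spec, X, y, 0.0)
        _, var = predict(m, rng.uniform(-3, 3, (50, 2)))
        assert np.all(var <= 1.5 + 1e-9)

    def test_symmetric_training_symmetric_midpoint(self):
        spec = KernelSpec("se_ard", 1.0, np.array([1.0]), 0.0)
        X = np.array([[-1.0], [1.0]])
        y = np.array([2.0, 2.0])
        m = GPModel(spec, X, y, 0.0)
        mu0, _ = predict(m, np.array([0.0]))
        mu_l, _ = predict(m, np.array([-0.3]))
        mu_r, _ = predict(m, np.array([0.3]))
        assert mu_l == pytest.approx(mu_r, rel=1e-10)
        assert mu0 > 0

    @pytest.mark.parametrize("family", KERNEL_FAMILIES)
    def test_matches_explicit_conditioning_oracle(self, family):
        rng = np.random.default_rng(8)
        X = rng.uniform(-2, 2, (12, 3))
        y = rng.standard_normal(12)
        spec = make_spec(family)
        mean_c = float(y.mean())
        m = GPModel(spec, X, y, mean_c)
        Xs = rng.uniform(-2, 2, (5, 3))
        mu, var = predict(m, Xs)
        # direct joint-normal conditioning with explicit inverses
        K = kernel_matrix(spec, X, X) + (spec.noise_variance + 1e-10) * np.eye(12)
        Ks = kernel_matrix(spec, Xs, X)
        Kss = kernel_matrix(spec, Xs, Xs)
        Kinv = np.linalg.inv(K)
        mu_o = mean_c + Ks @ Kinv @ (y - mean_c)
        var_o = np.diag(Kss - Ks @ Kinv @ Ks.T)
        assert np.allclose(mu, mu_o, atol=1e-8)
        assert np.allclose(var, np.maximum(var_o, 0), atol=1e-8)


class TestTraining:
    def test_improves_on_initialization_and_reproducible(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(-1, 1, (30, 2))
        y = np.sin(2 * X[:, 0]) + 0.1 * rng.standard_normal(30)
        from capsidfit.gp import default_spec

        m = train_gp("matern52_ard", X, y, seed=3)
        init = default_spec("matern52_ard", X, y)
        assert nlml(m) <= nlml(GPModel(init, X, y, float(y.mean()))) + 1e-9
        m2 = train_gp("matern52_ard", X, y, seed=3)
        assert np.allclose(m.kernel.lengthscales, m2.kernel.lengthscales)
        assert m.kernel.signal_variance == pytest.approx(m2.kernel.signal_variance)

    def test_recovers_se_ard_lengthscales_within_factor_two(self):
        rng = np.random.default_rng(10)
        true = KernelSpec("se_ard", 2.0, np.array([0.5, 1.5]), 1e-6)
        X = rng.uniform(-3, 3, (200, 2))
        K = kernel_matrix(true, X, X) + 1e-6 * np.eye(200)
        y = np.linalg.cholesky(K) @ rng.standard_normal(200)
        m = train_gp("se_ard", X, y, seed=1)
        for est, tru in zip(m.kernel.lengthscales, true.lengthscales):
            assert tru / 2 <= est <= tru * 2

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            train_gp("se_ard", np.zeros((1, 2)), np.zeros(1), seed=0)


class TestSerialization:
    def test_model_round_trip(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(-1, 1, (8, 3))
        y = rng.standard_normal(8)
        spec = make_spec("gabor_ard")
        m = GPModel(spec, X, y, float(y.mean()))
        back = GPModel.from_dict(m.to_dict())
        assert back.kernel.to_dict() == spec.to_dict()
        mu1, v1 = predict(m, X[:3])
        mu2, v2 = predict(back, X[:3])
        assert np.allclose(mu1, mu2) and np.allclose(v1, v2)
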