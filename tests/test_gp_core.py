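"""Exact-GP machinery: kernels, marginal likelihood, training, prediction."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from edmgp.gp import (
    RBF,
    ConfigurationError,
    GPRegression,
    Linear,
    Matern32,
    NumericalError,
    Sum,
    ctg_composite_kernel,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


class TestKernelEvaluation:
    def test_rbf_zero_distance_returns_signal_variance(self):
        k = RBF(variance=2.5, lengthscales=[0.7, 3.0], input_dim=2)
        x = np.array([[1.0, -2.0]])
        assert k(x, x)[0, 0] == pytest.approx(2.5)

    def test_matern32_zero_distance(self):
        k = Matern32(variance=1.0, lengthscales=0.3)
        x = np.array([[0.5]])
        assert k(x, x)[0, 0] == pytest.approx(1.0)

    def test_rbf_unit_distance(self):
        k = RBF(variance=1.0, lengthscales=1.0)
        v = k(np.array([[0.0]]), np.array([[1.0]]))[0, 0]
        assert v == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_composite_kernel_at_origin(self):
        # zero distance and zero linear term: alpha1^2 + alpha2^2 + 0
        k = ctg_composite_kernel(input_dim=2, alpha1_sq=1.5, alpha2_sq=0.5)
        x = np.zeros((1, 2))
        assert k(x, x)[0, 0] == pytest.approx(2.0)

    def test_kernel_matrix_shape_and_symmetry(self, rng):
        A = rng.standard_normal((7, 3))
        B = rng.standard_normal((4, 3))
        for k in (RBF(1.0, [1, 2, 3]), Matern32(2.0, [1, 1, 0.5]), Linear([1, 2, 1])):
            assert k(A, B).shape == (7, 4)
            KAA = k(A, A)
            np.testing.assert_allclose(KAA, KAA.T, atol=1e-12)

    def test_dimension_mismatch_raises(self, rng):
        k = RBF(1.0, [1.0, 1.0])
        with pytest.raises(ValueError, match="dimensionality"):
            k(rng.standard_normal((3, 2)), rng.standard_normal((3, 5)))

    def test_nonpositive_hyperparameter_rejected(self):
        with pytest.raises(ConfigurationError):
            RBF(variance=-1.0)
        with pytest.raises(ConfigurationError):
            Matern32(1.0, lengthscales=[1.0, 0.0])

    @pytest.mark.parametrize("kern", [
        RBF(1.3, [0.5, 2.0]),
        Matern32(0.7, [1.0, 0.3]),
        Sum([RBF(1.0, [1.0, 1.0]), Linear([0.5, 0.5])]),
        ctg_composite_kernel(input_dim=2),
    ])
    def test_psd_up_to_jitter(self, kern, rng):
        A = rng.standard_normal((30, 2)) * 2
        K = kern(A, A)
        eig = np.linalg.eigvalsh(K)
        assert eig.min() >= -1e-8 * np.trace(K)

    def test_ard_relevance_decreases_with_lengthscale(self):
        k = RBF(1.0, [0.5, 1.0, 4.0])
        r = k.relevance
        assert r[0] > r[1] > r[2]


class TestLogMarginalLikelihood:
    def test_single_standard_normal_point(self):
        gp = GPRegression(np.zeros((1, 1)), [0.0], RBF(1.0, 1.0), noise_variance=0.0)
        # K = [[1]] (+ tiny jitter): standard-normal log density at 0
        assert gp.log_marginal_likelihood() == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-6)

    def test_matches_multivariate_normal_oracle(self, rng):
        """Eq-by-eq oracle: direct MVN log density with explicit K."""
        for trial in range(50):
            n = int(rng.integers(2, 30))
            X = rng.standard_normal((n, 2))
            y = rng.standard_normal(n)
            kern = RBF(float(rng.uniform(0.5, 2)), rng.uniform(0.3, 3, size=2))
            noise = float(rng.uniform(0.05, 1.0))
            gp = GPRegression(X, y, kern, noise)
            K = kern(X, X) + noise * np.eye(n)
            oracle = multivariate_normal(mean=np.zeros(n), cov=K, allow_singular=True).logpdf(y)
            assert gp.log_marginal_likelihood() == pytest.approx(oracle, abs=1e-6)

    def test_data_fit_term_scales_quadratically(self, rng):
        X = rng.standard_normal((8, 1))
        y = rng.standard_normal(8)
        kern = RBF(1.0, 1.0)
        gp1 = GPRegression(X, y, kern, 0.5)
        gp2 = GPRegression(X, 3.0 * y, kern, 0.5)
        K = kern(X, X) + 0.5 * np.eye(8)
        datafit = -0.5 * y @ np.linalg.solve(K, y)
        # scaling y by c changes only the data-fit term, by c^2
        assert gp2.log_marginal_likelihood() - gp1.log_marginal_likelihood() == pytest.approx(
            (9 - 1) * datafit, rel=1e-6
        )

    def test_gradient_matches_finite_differences(self, rng):
        X = rng.standard_normal((12, 2))
        y = rng.standard_normal(12)
        gp = GPRegression(X, y, Sum([RBF(1.0, [1.0, 2.0]), Linear([0.5, 0.5])]), 0.3)
        lp = np.concatenate([gp.kernel.get_log_params(), [np.log(gp.noise_variance)]])
        f0, g = gp._lml_and_grad(lp.copy())
        eps = 1e-6
        for i in range(lp.size):
            lp_p, lp_m = lp.copy(), lp.copy()
            lp_p[i] += eps
            lp_m[i] -= eps
            fd = (gp._lml_and_grad(lp_p)[0] - gp._lml_and_grad(lp_m)[0]) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestPredict:
    def test_noise_free_interpolation(self, rng):
        X = rng.uniform(-2, 2, (6, 1))
        y = np.sin(X[:, 0])
        gp = GPRegression(X, y, RBF(1.0, 1.0), noise_variance=0.0)
        m, v = gp.predict(X[:1])
        assert m[0] == pytest.approx(y[0], abs=1e-4)
        assert v[0] == pytest.approx(0.0, abs=1e-4)

    def test_prior_reversion_far_from_data(self):
        X = np.zeros((3, 1))
        y = np.array([1.0, 1.1, 0.9])
        gp = GPRegression(X, y, RBF(2.0, 0.5), noise_variance=0.1)
        m, v = gp.predict(np.array([[50.0]]))
        assert m[0] == pytest.approx(0.0, abs=1e-8)
        assert v[0] == pytest.approx(2.0, abs=1e-8)

    def test_matches_gaussian_conditioning_oracle(self, rng):
        """Brute-force block conditioning of the joint Gaussian."""
        X = rng.standard_normal((4, 1))
        Xs = rng.standard_normal((3, 1))
        y = rng.standard_normal(4)
        kern = RBF(1.2, 0.8)
        noise = 0.2
        gp = GPRegression(X, y, kern, noise)
        m, C = gp.predict(Xs, full_cov=True)
        Kff = kern(X, X) + noise * np.eye(4)
        Ksf = kern(Xs, X)
        Kss = kern(Xs, Xs)
        m_or = Ksf @ np.linalg.solve(Kff, y)
        C_or = Kss - Ksf @ np.linalg.solve(Kff, Ksf.T)
        np.testing.assert_allclose(m, m_or, atol=1e-7)
        np.testing.assert_allclose(C, C_or, atol=1e-6)

    def test_posterior_contraction_at_training_inputs(self, rng):
        X = rng.standard_normal((25, 1))
        y = rng.standard_normal(25)
        gp = GPRegression(X, y, RBF(1.7, 1.0), noise_variance=0.3)
        _, v = gp.predict(X)
        assert np.all(v <= 1.7 + 1e-9)


class TestFit:
    def test_objective_never_worsens(self, rng):
        X = rng.uniform(-3, 3, (30, 1))
        y = np.sin(X[:, 0]) + 0.1 * rng.standard_normal(30)
        gp = GPRegression(X, y, RBF(1.0, 1.0), 0.5)
        before = gp.log_marginal_likelihood()
        gp.fit(n_restarts=2, seed=0, maxiter=50)
        assert gp.log_marginal_likelihood() >= before - 1e-9

    def test_fit_is_reproducible(self, rng):
        X = rng.uniform(-3, 3, (25, 1))
        y = np.sin(X[:, 0]) + 0.1 * rng.standard_normal(25)
        results = []
        for _ in range(2):
            gp = GPRegression(X.copy(), y.copy(), RBF(1.0, 1.0), 0.5)
            gp.fit(n_restarts=2, seed=7, maxiter=60)
            results.append(np.concatenate([gp.kernel.get_log_params(), [gp.noise_variance]]))
        np.testing.assert_array_equal(results[0], results[1])

    def test_constant_targets_fit_with_small_noise(self):
        X = np.linspace(0, 1, 20)[:, None]
        gp = GPRegression(X, np.full(20, 3.3) - 3.3, RBF(1.0, 1.0), 0.5)
        gp.fit(n_restarts=1, seed=0, maxiter=100)
        assert gp.noise_variance < 0.1

    def test_too_few_points_raises(self):
        gp = GPRegression(np.zeros((1, 1)), [1.0], RBF(1.0, 1.0), 0.1)
        with pytest.raises(ValueError, match="at least 2"):
            gp.fit()


def test_hyperparameter_recovery_from_known_gp():
    """Simulation-based recovery: log-hyperparameters within +-0.5 nats of
    truth in at least 80% of seeded replicates at n=200."""
    true = dict(sf2=1.0, ell=0.5, noise=0.01)
    kern_true = RBF(true["sf2"], true["ell"])
    hits = 0
    n_rep = 20
    for rep in range(n_rep):
        rng = np.random.default_rng(1000 + rep)
        # wide domain (32 true length-scales) so the signal variance is
        # statistically identifiable from a single draw
        X = rng.uniform(-8, 8, (200, 1))
        K = kern_true(X, X) + true["noise"] * np.eye(200)
        y = rng.multivariate_normal(np.zeros(200), K)
        gp = GPRegression(X, y, RBF(0.7, 1.0), 0.1)
        gp.fit(n_restarts=2, seed=rep, maxiter=150)
        lp = gp.kernel.get_log_params()
        ok = (
            abs(lp[0] - np.log(true["sf2"])) < 0.5
            and abs(lp[1] - np.log(true["ell"])) < 0.5
            and abs(np.log(gp.noise_variance) - np.log(true["noise"])) < 0.5
        )
        hits += ok
    assert hits >= 0.8 * n_rep


def test_config_roundtrip_is_plain_text(rng):
    gp = GPRegression(rng.standard_normal((5, 2)), rng.standard_normal(5),
                      ctg_composite_kernel(input_dim=2), 0.2)
    cfg = gp.to_config()
    assert "noise_variance" in cfg and "=" in cfg
    assert all(ord(c) < 128 for c in cfg)
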