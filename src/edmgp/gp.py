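"""Exact Gaussian-process regression: kernels, marginal likelihood, training, prediction.

A zero-mean GP prior ``f ~ GP(0, k)`` observed through additive white Gaussian
noise ``y = f(x) + eps``, ``eps ~ N(0, sigma_eps^2)``.  Hyperparameters are
trained by maximizing the log marginal likelihood

    log p(y | X, theta) = -1/2 y^T K^-1 y - 1/2 log|K| - n/2 log 2pi,

with ``K = K_ff + sigma_eps^2 I``, using L-BFGS on log-transformed parameters
with seeded random restarts.  The predictive distribution at test inputs is the
usual Gaussian conditional (posterior mean ``K_*f K^-1 y`` and covariance
``K_** - K_*f K^-1 K_f*``).

Kernels implemented: ARD squared-exponential (RBF), ARD Matern nu=3/2, linear,
and sums thereof.  The per-dimension ARD relevance is ``r_q = 1/ell_q``.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.spatial.distance import cdist

__all__ = [
    "Kernel",
    "RBF",
    "Matern32",
    "Linear",
    "Sum",
    "GPRegression",
    "ctg_composite_kernel",
    "NumericalError",
    "ConfigurationError",
]

JITTER_START = 1e-8
JITTER_MAX = 1e-2
SQRT3 = np.sqrt(3.0)


class NumericalError(RuntimeError):
    """Linear-algebra failure that persists after maximum jitter escalation."""


class ConfigurationError(ValueError):
    """Invalid kernel or model configuration (e.g. non-positive hyperparameter)."""


def chol_with_jitter(K: np.ndarray) -> Tuple[np.ndarray, float]:
    """Cholesky of a symmetric PSD matrix with escalating diagonal jitter.

    Starts at ``1e-8 * mean(diag)`` and escalates tenfold up to ``1e-2``;
    raises :class:`NumericalError` if the factorization still fails.
    """
    diag_mean = float(np.mean(np.diag(K)))
    if not np.isfinite(diag_mean) or diag_mean <= 0:
        diag_mean = 1.0
    last_err: Optional[Exception] = None
    try:
        return cholesky(K, lower=True), 0.0
    except np.linalg.LinAlgError as err:
        last_err = err
    jitter = JITTER_START * diag_mean
    while jitter <= JITTER_MAX * diag_mean * 1.0001:
        try:
            L = cholesky(K + jitter * np.eye(K.shape[0]), lower=True)
            return L, jitter
        except np.linalg.LinAlgError as err:
            last_err = err
            jitter *= 10.0
    raise NumericalError(
        f"Cholesky failed even with jitter {jitter/diag_mean:.1e} x mean diagonal"
    ) from last_err


def _check_positive(name: str, value: np.ndarray | float) -> None:
    if np.any(np.asarray(value) <= 0):
        raise ConfigurationError(f"{name} must be strictly positive, got {value}")


def _as_2d(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    return A


class Kernel:
    """Base class: covariance evaluation plus log-space hyperparameter gradients."""

    input_dim: int

    def __call__(self, A: np.ndarray, B: Optional[np.ndarray] = None) -> np.ndarray:
        raise NotImplementedError

    def diag(self, A: np.ndarray) -> np.ndarray:
        A = _as_2d(A)
        return np.diag(self(A, A)).copy()

    # --- hyperparameters, stored/optimized in log space -------------------
    def get_log_params(self) -> np.ndarray:
        raise NotImplementedError

    def set_log_params(self, lp: np.ndarray) -> None:
        raise NotImplementedError

    def param_names(self) -> List[str]:
        raise NotImplementedError

    def gradients(self, A: np.ndarray) -> List[np.ndarray]:
        """dK(A,A)/d(log theta_i) for each hyperparameter, in param order."""
        raise NotImplementedError

    def _check_dims(self, A: np.ndarray) -> np.ndarray:
        A = _as_2d(A)
        if A.shape[1] != self.input_dim:
            raise ValueError(
                f"input dimensionality {A.shape[1]} does not match kernel "
                f"input_dim {self.input_dim}"
            )
        return A

    def __add__(self, other: "Kernel") -> "Sum":
        return Sum([self, other])


class RBF(Kernel):
    """ARD squared-exponential kernel.

    ``k(x, x') = sf2 * exp(-1/2 sum_q (x_q - x'_q)^2 / ell_q^2)``
    """

    def __init__(self, variance: float = 1.0, lengthscales=1.0, input_dim: int = 1):
        lengthscales = np.atleast_1d(np.asarray(lengthscales, dtype=float))
        if lengthscales.size == 1 and input_dim > 1:
            lengthscales = np.full(input_dim, lengthscales[0])
        self.input_dim = max(input_dim, lengthscales.size)
        if lengthscales.size != self.input_dim:
            raise ConfigurationError("lengthscales size must match input_dim")
        _check_positive("variance", variance)
        _check_positive("lengthscales", lengthscales)
        self.variance = float(variance)
        self.lengthscales = lengthscales

    @property
    def relevance(self) -> np.ndarray:
        """ARD relevance weights r_q = 1 / ell_q."""
        return 1.0 / self.lengthscales

    def __call__(self, A, B=None):
        A = self._check_dims(A)
        B = A if B is None else self._check_dims(B)
        D2 = cdist(A / self.lengthscales, B / self.lengthscales, "sqeuclidean")
        return self.variance * np.exp(-0.5 * D2)

    def get_log_params(self):
        return np.concatenate(([np.log(self.variance)], np.log(self.lengthscales)))

    def set_log_params(self, lp):
        self.variance = float(np.exp(lp[0]))
        self.lengthscales = np.exp(np.asarray(lp[1 : 1 + self.input_dim]))

    def param_names(self):
        return ["rbf.variance"] + [f"rbf.lengthscale[{q}]" for q in range(self.input_dim)]

    def gradients(self, A):
        A = self._check_dims(A)
        K = self(A, A)
        grads = [K.copy()]
        for q in range(self.input_dim):
            d2q = (A[:, q : q + 1] - A[:, q : q + 1].T) ** 2
            grads.append(K * d2q / self.lengthscales[q] ** 2)
        return grads


class Matern32(Kernel):
    """ARD Matern kernel with nu = 3/2.

    ``k(d) = sf2 * (1 + sqrt(3) d) * exp(-sqrt(3) d)`` with the scaled distance
    ``d = sqrt(sum_q (x_q - x'_q)^2 / ell_q^2)`` (Mahalanobis form, so the ARD
    matrix holds inverse-squared length-scales on its diagonal).
    """

    def __init__(self, variance: float = 1.0, lengthscales=1.0, input_dim: int = 1):
        lengthscales = np.atleast_1d(np.asarray(lengthscales, dtype=float))
        if lengthscales.size == 1 and input_dim > 1:
            lengthscales = np.full(input_dim, lengthscales[0])
        self.input_dim = max(input_dim, lengthscales.size)
        if lengthscales.size != self.input_dim:
            raise ConfigurationError("lengthscales size must match input_dim")
        _check_positive("variance", variance)
        _check_positive("lengthscales", lengthscales)
        self.variance = float(variance)
        self.lengthscales = lengthscales

    def _scaled_dist(self, A, B):
        return cdist(A / self.lengthscales, B / self.lengthscales, "euclidean")

    def __call__(self, A, B=None):
        A = self._check_dims(A)
        B = A if B is None else self._check_dims(B)
        r = self._scaled_dist(A, B)
        return self.variance * (1.0 + SQRT3 * r) * np.exp(-SQRT3 * r)

    def get_log_params(self):
        return np.concatenate(([np.log(self.variance)], np.log(self.lengthscales)))

    def set_log_params(self, lp):
        self.variance = float(np.exp(lp[0]))
        self.lengthscales = np.exp(np.asarray(lp[1 : 1 + self.input_dim]))

    def param_names(self):
        return ["mat32.variance"] + [
            f"mat32.lengthscale[{q}]" for q in range(self.input_dim)
        ]

    def gradients(self, A):
        A = self._check_dims(A)
        r = self._scaled_dist(A, A)
        E = np.exp(-SQRT3 * r)
        K = self.variance * (1.0 + SQRT3 * r) * E
        grads = [K.copy()]
        # dk/d(log ell_q) = 3 * sf2 * exp(-sqrt3 r) * dq^2 / ell_q^2  (finite at r=0)
        for q in range(self.input_dim):
            d2q = (A[:, q : q + 1] - A[:, q : q + 1].T) ** 2
            grads.append(3.0 * self.variance * E * d2q / self.lengthscales[q] ** 2)
        return grads


class Linear(Kernel):
    """Linear kernel ``k(x, x') = sum_q w_q x_q x'_q`` with positive weights."""

    def __init__(self, weights=1.0, input_dim: int = 1):
        weights = np.atleast_1d(np.asarray(weights, dtype=float))
        if weights.size == 1 and input_dim > 1:
            weights = np.full(input_dim, weights[0])
        self.input_dim = max(input_dim, weights.size)
        if weights.size != self.input_dim:
            raise ConfigurationError("weights size must match input_dim")
        _check_positive("weights", weights)
        self.weights = weights

    def __call__(self, A, B=None):
        A = self._check_dims(A)
        B = A if B is None else self._check_dims(B)
        return (A * self.weights) @ B.T

    def get_log_params(self):
        return np.log(self.weights)

    def set_log_params(self, lp):
        self.weights = np.exp(np.asarray(lp[: self.input_dim]))

    def param_names(self):
        return [f"linear.weight[{q}]" for q in range(self.input_dim)]

    def gradients(self, A):
        A = self._check_dims(A)
        return [
            self.weights[q] * np.outer(A[:, q], A[:, q]) for q in range(self.input_dim)
        ]


class Sum(Kernel):
    """Sum of kernels sharing the same input space."""

    def __init__(self, parts: Sequence[Kernel]):
        if not parts:
            raise ConfigurationError("Sum kernel needs at least one part")
        dims = {k.input_dim for k in parts}
        if len(dims) != 1:
            raise ConfigurationError("all summed kernels must share input_dim")
        self.parts = list(parts)
        self.input_dim = self.parts[0].input_dim

    def __call__(self, A, B=None):
        return sum(k(A, B) for k in self.parts)

    def get_log_params(self):
        return np.concatenate([k.get_log_params() for k in self.parts])

    def set_log_params(self, lp):
        i = 0
        for k in self.parts:
            n = k.get_log_params().size
            k.set_log_params(lp[i : i + n])
            i += n

    def param_names(self):
        return [n for k in self.parts for n in k.param_names()]

    def gradients(self, A):
        return [g for k in self.parts for g in k.gradients(A)]


def ctg_composite_kernel(
    input_dim: int = 2,
    alpha1_sq: float = 1.0,
    alpha2_sq: float = 1.0,
    betas: Optional[Sequence[float]] = None,
) -> Sum:
    """Composite covariance for FHR imputation on 2-D inputs (time, UA).

    Sum of a Matern-3/2 term (rapid variation), an RBF term (slow variation)
    and a linear term (trend):

        k = alpha1^2 Matern32(Mahalanobis dist under Lambda1)
          + alpha2^2 RBF(Mahalanobis dist under Lambda2)
          + x_i' Lambda3 x_j

    with diagonal ARD matrices ``Lambda1 = diag(beta1, beta2)``,
    ``Lambda2 = diag(beta3, beta4)``, ``Lambda3 = diag(beta5, beta6)``; the
    Lambda1/Lambda2 entries are inverse-squared length-scales.  With
    ``input_dim=1`` the UA coordinate is dropped (time-only variant) and only
    betas 1, 3, 5 apply.
    """
    if betas is None:
        betas = [1.0] * (3 * input_dim)
    betas = np.asarray(betas, dtype=float)
    if betas.size != 3 * input_dim:
        raise ConfigurationError(f"need {3 * input_dim} beta parameters")
    _check_positive("betas", betas)
    ell1 = 1.0 / np.sqrt(betas[:input_dim])
    ell2 = 1.0 / np.sqrt(betas[input_dim : 2 * input_dim])
    w3 = betas[2 * input_dim :]
    return Sum(
        [
            Matern32(alpha1_sq, ell1, input_dim=input_dim),
            RBF(alpha2_sq, ell2, input_dim=input_dim),
            Linear(w3, input_dim=input_dim),
        ]
    )


class GPRegression:
    """Exact zero-mean GP regression with Gaussian observation noise.

    Parameters
    ----------
    X:
        Training inputs, shape (n, Q) (1-D arrays are treated as a column).
    y:
        Training targets, shape (n,).
    kernel:
        Covariance function.
    noise_variance:
        Initial observation-noise variance ``sigma_eps^2``.
    """

    def __init__(self, X, y, kernel: Kernel, noise_variance: float = 1.0):
        self.X = _as_2d(X)
        self.y = np.asarray(y, dtype=float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError("number of training inputs must equal number of targets")
        if noise_variance < 0:
            raise ConfigurationError("noise variance must be non-negative")
        self.kernel = kernel
        self.noise_variance = float(noise_variance)
        self.warning_flag: Optional[str] = None

    # ------------------------------------------------------------------
    def _K(self) -> np.ndarray:
        return self.kernel(self.X, self.X) + self.noise_variance * np.eye(self.X.shape[0])

    def log_marginal_likelihood(self) -> float:
        n = self.y.size
        L, _ = chol_with_jitter(self._K())
        alpha = cho_solve((L, True), self.y)
        return float(
            -0.5 * self.y @ alpha
            - np.sum(np.log(np.diag(L)))
            - 0.5 * n * np.log(2 * np.pi)
        )

    def _lml_and_grad(self, lp: np.ndarray) -> Tuple[float, np.ndarray]:
        """Negative LML and its gradient wrt [kernel log-params, log noise]."""
        self.kernel.set_log_params(lp[:-1])
        self.noise_variance = float(np.exp(lp[-1]))
        n = self.y.size
        L, _ = chol_with_jitter(self._K())
        alpha = cho_solve((L, True), self.y)
        lml = (
            -0.5 * self.y @ alpha
            - np.sum(np.log(np.diag(L)))
            - 0.5 * n * np.log(2 * np.pi)
        )
        Kinv = cho_solve((L, True), np.eye(n))
        W = np.outer(alpha, alpha) - Kinv  # dL/dK = 0.5 * W
        grads = self.kernel.gradients(self.X)
        g = np.empty(lp.size)
        for i, dK in enumerate(grads):
            g[i] = 0.5 * np.sum(W * dK)
        g[-1] = 0.5 * np.trace(W) * self.noise_variance
        return -float(lml), -g

    def fit(
        self,
        n_restarts: int = 3,
        seed: int = 0,
        maxiter: int = 200,
        noise_floor: float = 1e-8,
    ) -> "GPRegression":
        """Maximize the log marginal likelihood by L-BFGS with seeded restarts.

        The returned model's objective is never worse than at initialization;
        if the optimizer fails, the best iterate found is kept and
        ``warning_flag`` is set.
        """
        if self.y.size < 2:
            raise ValueError("need at least 2 training points to fit")
        rng = np.random.default_rng(seed)
        lp0 = np.concatenate(
            [self.kernel.get_log_params(), [np.log(max(self.noise_variance, noise_floor))]]
        )
        bounds = [(-15.0, 15.0)] * lp0.size
        bounds[-1] = (np.log(noise_floor), 15.0)
        best_lp, best_f = lp0.copy(), self._lml_and_grad(lp0)[0]
        init_f = best_f
        any_success = False
        for r in range(max(1, n_restarts)):
            start = lp0 if r == 0 else lp0 + rng.normal(0, 0.5, size=lp0.size)
            try:
                res = optimize.minimize(
                    self._lml_and_grad,
                    start,
                    jac=True,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": maxiter},
                )
            except NumericalError:
                continue
            if np.isfinite(res.fun) and res.fun < best_f:
                best_f, best_lp = res.fun, res.x.copy()
            any_success = any_success or bool(res.success)
        self.kernel.set_log_params(best_lp[:-1])
        self.noise_variance = float(np.exp(best_lp[-1]))
        if not any_success:
            self.warning_flag = "optimizer did not report convergence; best iterate kept"
        if best_f > init_f + 1e-9:  # pragma: no cover - contract guard
            raise AssertionError("objective worsened during fit")
        return self

    def predict(
        self,
        Xs,
        full_cov: bool = False,
        include_noise: bool = False,
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Predictive posterior mean and (co)variance at test inputs.

        Returns ``(mean, cov)`` if ``full_cov`` else ``(mean, var)``.  Small
        negative variances (> -1e-6 * signal scale) are clipped to zero with a
        warning; larger negatives raise :class:`NumericalError`.
        """
        Xs = _as_2d(Xs)
        L, _ = chol_with_jitter(self._K())
        Ks = self.kernel(Xs, self.X)
        alpha = cho_solve((L, True), self.y)
        mean = Ks @ alpha
        v = solve_triangular(L, Ks.T, lower=True)
        if full_cov:
            cov = self.kernel(Xs, Xs) - v.T @ v
            if include_noise:
                cov = cov + self.noise_variance * np.eye(Xs.shape[0])
            cov = self._clip_variances(cov, diag=False)
            return mean, cov
        var = self.kernel.diag(Xs) - np.sum(v**2, axis=0)
        if include_noise:
            var = var + self.noise_variance
        var = self._clip_variances(var, diag=True)
        return mean, var

    def _clip_variances(self, v: np.ndarray, diag: bool) -> np.ndarray:
        d = np.diag(v).copy() if not diag else v
        scale = max(float(np.max(np.abs(d))), 1.0)
        tol = 1e-6 * scale
        if np.any(d < -tol):
            raise NumericalError(
                f"negative predictive variance {d.min():.3e} below tolerance -{tol:.1e}"
            )
        if np.any(d < 0):
            warnings.warn("clipping slightly negative predictive variances to zero")
            if diag:
                v = np.maximum(v, 0.0)
            else:
                np.fill_diagonal(v, np.maximum(d, 0.0))
        return v

    # --- plain-text config round-trip ---------------------------------
    def to_config(self) -> str:
        lines = [f"noise_variance={self.noise_variance!r}"]
        for name, val in zip(self.kernel.param_names(), np.exp(self.kernel.get_log_params())):
            lines.append(f"{name}={val!r}")
        return "\n".join(lines) + "\n"
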