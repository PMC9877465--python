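"""Attractor-manifold reconstruction from a single time series.

Two stages:

1. :func:`delay_embed` — Takens-style delay embedding.  Row t of the N x E
   matrix ``M_init`` is ``[x(t), x(t - tau), ..., x(t - (E-1) tau)]`` with
   ``N = T - (E-1) tau``.  A generous E (default 20) with tau = 1 satisfies
   the embedding requirement without a grid search but leaves the coordinates
   highly redundant.
2. :func:`reconstruct_manifold` — compress ``M_init`` with a Bayesian GPLVM
   (ARD RBF kernel, variational inference with inducing points).  The ARD
   weights of irrelevant latent dimensions shrink toward zero, so the number
   of retained dimensions estimates the attractor dimensionality, and the
   variational posterior mean over the retained dimensions is the
   reconstructed manifold ``M_GP``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .gplvm import BayesianGPLVM, GPLVMResult
from .series import TimeSeries, as_series

__all__ = [
    "DelayEmbedding",
    "LatentManifold",
    "ManifoldConfig",
    "delay_embed",
    "reconstruct_manifold",
    "manifold_from_series",
    "effective_dimension",
    "variance_explained",
]


@dataclass
class DelayEmbedding:
    """Delay-coordinate matrix ``M_init`` with its lag/dimension metadata."""

    matrix: np.ndarray        # (N, E), row t = [x(t), x(t-tau), ..., x(t-(E-1)tau)]
    E: int
    tau: int
    source_length: int
    time_index: np.ndarray    # sample index of column 0 of each row

    @property
    def N(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ManifoldConfig:
    """Settings for the GPLVM compression stage.

    ``latent_dim=None`` initializes the latent dimensionality at E (no
    compression is forced a priori).  ``max_points`` bounds the number of
    embedding rows used in the variational fit (time-strided subsample) to
    keep the O(N M^2 Q) bound affordable; the threshold is the normalized
    relevance below which an ARD dimension counts as switched off.
    """

    latent_dim: Optional[int] = None
    n_inducing: int = 40
    max_points: int = 500
    maxiter: int = 400
    threshold: float = 0.05
    standardize: bool = True
    seed: int = 0


@dataclass
class LatentManifold:
    """Posterior latent representation ``M_GP`` with ARD relevances."""

    mean: np.ndarray            # (N, Q) posterior means, all latent dimensions
    variance: np.ndarray        # (N, Q) posterior variances
    relevance: np.ndarray       # (Q,) ARD relevance r_q = 1/ell_q
    retained: np.ndarray        # indices of retained dimensions
    effective_dim: int
    elbo: float
    elbo_init: float
    config: ManifoldConfig
    E: int
    tau: int
    converged: bool = True
    standardized: bool = True
    time_index: Optional[np.ndarray] = None
    fit_targets: Optional[np.ndarray] = field(default=None, repr=False)
    _gplvm: Optional[GPLVMResult] = field(default=None, repr=False)

    @property
    def points(self) -> np.ndarray:
        """Reconstructed manifold: posterior means of the retained dimensions."""
        return self.mean[:, self.retained]

    # --- plain-text serialization -------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        np.savetxt(path, self.points, fmt="%.8g")
        meta = {
            "E": self.E,
            "tau": self.tau,
            "relevance": self.relevance.tolist(),
            "retained": self.retained.tolist(),
            "effective_dim": int(self.effective_dim),
            "elbo": self.elbo,
            "seed": self.config.seed,
            "threshold": self.config.threshold,
            "standardized": self.standardized,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2)
        )


def delay_embed(series, E: int, tau: int = 1) -> DelayEmbedding:
    """Takens delay embedding of a complete, uniformly sampled series.

    Raises on missing samples (impute first) and on series shorter than the
    embedding window.
    """
    ts = as_series(series)
    if ts.missing.any():
        raise ValueError(
            "series contains missing samples inside the embedding window; "
            "run imputation or preprocessing first"
        )
    if E < 1 or tau < 1:
        raise ValueError("E and tau must be positive integers")
    T = ts.n
    N = T - (E - 1) * tau
    if N < 1:
        raise ValueError(f"series too short: T={T} < (E-1)*tau+1={(E-1)*tau+1}")
    x = ts.values
    cols = [x[(E - 1) * tau - j * tau : T - j * tau] for j in range(E)]
    M = np.column_stack(cols)  # column j = x(t - j*tau)
    time_index = np.arange((E - 1) * tau, T)
    return DelayEmbedding(matrix=M, E=E, tau=tau, source_length=T, time_index=time_index)


def reconstruct_manifold(
    embedding: DelayEmbedding, config: Optional[ManifoldConfig] = None
) -> LatentManifold:
    """Compress a delay embedding to a latent manifold with a Bayesian GPLVM."""
    config = config or ManifoldConfig()
    if embedding.E < 2:
        raise ValueError("embedding dimension E must be >= 2 for compression")
    Y = embedding.matrix
    N = Y.shape[0]
    if N < 50:
        raise ValueError(f"need >= 50 embedded points for a stable fit, got {N}")
    Q = config.latent_dim or embedding.E

    # time-strided subsample keeps the attractor coverage while bounding cost
    if N > config.max_points:
        idx = np.linspace(0, N - 1, config.max_points).round().astype(int)
    else:
        idx = np.arange(N)
    model = BayesianGPLVM(
        Y[idx],
        latent_dim=Q,
        n_inducing=min(config.n_inducing, idx.size),
        seed=config.seed,
    )
    res = model.fit(maxiter=config.maxiter)

    relevance = res.relevance
    manifold = LatentManifold(
        mean=res.mean,
        variance=res.variance,
        relevance=relevance,
        retained=np.arange(Q),
        effective_dim=Q,
        elbo=res.elbo,
        elbo_init=res.elbo_init,
        config=config,
        E=embedding.E,
        tau=embedding.tau,
        converged=res.converged,
        time_index=embedding.time_index[idx],
        fit_targets=Y[idx] - Y[idx].mean(axis=0),
        _gplvm=res,
    )
    d_eff = effective_dimension(manifold, threshold=config.threshold)
    order = np.argsort(relevance)[::-1]
    manifold.retained = np.sort(order[:d_eff])
    manifold.effective_dim = d_eff
    return manifold


def manifold_from_series(
    series,
    E: int = 20,
    tau: int = 1,
    config: Optional[ManifoldConfig] = None,
) -> LatentManifold:
    """Standardize, delay-embed, and GPLVM-compress a series in one call.

    Standardization (zero mean, unit variance) keeps manifold coordinates and
    downstream distances comparable across records; disable it via
    ``config.standardize=False``.
    """
    config = config or ManifoldConfig()
    ts = as_series(series)
    if config.standardize:
        ts = ts.standardized()
    emb = delay_embed(ts, E=E, tau=tau)
    m = reconstruct_manifold(emb, config)
    m.standardized = config.standardize
    return m


def effective_dimension(manifold: LatentManifold, threshold: float = 0.05) -> int:
    """Count latent dimensions whose normalized ARD relevance exceeds ``threshold``.

    Relevances are normalized by their maximum, so the count is invariant to
    the overall kernel scale.  Raises if the fit is degenerate (all
    relevances zero).
    """
    rel = np.asarray(manifold.relevance, dtype=float)
    mx = rel.max() if rel.size else 0.0
    if not np.isfinite(mx) or mx <= 0:
        raise ValueError("degenerate fit: all ARD relevances are zero")
    return int(np.sum(rel / mx > threshold))


def variance_explained(manifold: LatentManifold, dims) -> float:
    """Fraction of M_init variance explained by a GP map from chosen latent dims.

    Predicts the (centred) embedding matrix from the latent posterior means
    restricted to ``dims`` using the learned kernel and noise (a kernel
    smoother, no refit); returns ``1 - SSE/SST``.  Diagnostic for whether the
    retained dimensions preserve the signal that the full latent set carries.
    """
    from scipy.linalg import cho_solve

    from .gp import RBF, chol_with_jitter

    res = manifold._gplvm
    if res is None or manifold.fit_targets is None:
        raise ValueError("manifold does not carry its fitted GPLVM state")
    dims = np.atleast_1d(np.asarray(dims, dtype=int))
    Y = manifold.fit_targets
    X = manifold.mean[:, dims]
    w = res.ard_weights[dims]
    ell = 1.0 / np.sqrt(np.maximum(w, 1e-12))
    kern = RBF(res.signal_variance, ell, input_dim=dims.size)
    K = kern(X, X)
    L, _ = chol_with_jitter(K + res.noise_variance * np.eye(X.shape[0]))
    Yhat = K @ cho_solve((L, True), Y)
    sse = float(np.sum((Y - Yhat) ** 2))
    sst = float(np.sum(Y**2))
    return 1.0 - sse / sst
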