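"""FHR-UA interaction feature (Hausdorff distance between manifolds) and
conventional CTG comparison features.

The interaction feature is the Hausdorff distance

    H(A, B) = max( sup_a inf_b d(a, b),  sup_b inf_a d(a, b) )

between the reconstructed attractor manifolds of the FHR and UA signals —
two point sets in latent space.  Both manifolds are built from standardized
series so H is comparable across records; if their retained dimensionalities
differ, the lower-dimensional set is zero-padded to the higher dimension.

Comparison features (computed on FHR):

* STV — mean absolute successive difference of 2.5-s epoch averages
  (beat-scale variability), averaged minute-wise;
* LTV — mean minute-wise range (max - min) of the epoch averages;
* band energies of the Welch periodogram at 4 Hz over VLF 0-0.06 Hz,
  LF 0.06-0.3 Hz, MF 0.3-1 Hz, HF 1-2 Hz, plus the ratio LF/(MF+HF);
* approximate entropy and sample entropy (m=2, r=0.2 x SD).

For cohorts with an umbilical-artery pH label,
:func:`feature_ph_correlation` assembles the Pearson correlation matrix of
the features and pH.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import signal
from scipy.spatial.distance import cdist

from .manifold import ManifoldConfig, manifold_from_series
from .series import TimeSeries, as_series

__all__ = [
    "FeatureConfig",
    "hausdorff",
    "manifold_interaction",
    "baseline_features",
    "feature_ph_correlation",
    "approximate_entropy",
    "sample_entropy",
]

BANDS: Dict[str, tuple] = {
    "vlf": (0.0, 0.06),
    "lf": (0.06, 0.3),
    "mf": (0.3, 1.0),
    "hf": (1.0, 2.0),
}


@dataclass
class FeatureConfig:
    E: int = 10
    tau: int = 1
    manifold: ManifoldConfig = field(
        default_factory=lambda: ManifoldConfig(n_inducing=25, max_points=300, maxiter=200)
    )
    entropy_m: int = 2
    entropy_r_factor: float = 0.2
    welch_window_s: float = 120.0
    epoch_s: float = 2.5
    seed: int = 0


# ----------------------------------------------------------------------
def hausdorff(A: np.ndarray, B: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets (Euclidean)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.size == 0 or B.size == 0:
        raise ValueError("Hausdorff distance of an empty set is undefined")
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"point dimensionality mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    D = cdist(A, B)
    return float(max(D.min(axis=1).max(), D.min(axis=0).max()))


def _pad_to_dim(P: np.ndarray, d: int) -> np.ndarray:
    if P.shape[1] == d:
        return P
    pad = np.zeros((P.shape[0], d - P.shape[1]))
    return np.hstack([P, pad])


def manifold_interaction(
    fhr, ua, config: Optional[FeatureConfig] = None
) -> float:
    """Hausdorff distance between the FHR and UA attractor manifolds.

    Reconstructs both manifolds (standardized series, shared settings,
    per-channel seeds) and zero-pads the lower-dimensional one before
    computing H.
    """
    cfg = config or FeatureConfig()
    mc = cfg.manifold
    m_fhr = manifold_from_series(as_series(fhr), E=cfg.E, tau=cfg.tau, config=mc)
    mc_ua = ManifoldConfig(**{**mc.__dict__, "seed": mc.seed + 1})
    m_ua = manifold_from_series(as_series(ua), E=cfg.E, tau=cfg.tau, config=mc_ua)
    A, B = m_fhr.points, m_ua.points
    d = max(A.shape[1], B.shape[1])
    return hausdorff(_pad_to_dim(A, d), _pad_to_dim(B, d))


# ----------------------------------------------------------------------
def _epoch_averages(x: np.ndarray, fs: float, epoch_s: float) -> np.ndarray:
    k = int(round(epoch_s * fs))
    n_epochs = x.size // k
    return x[: n_epochs * k].reshape(n_epochs, k).mean(axis=1)


def short_long_term_variability(
    series: TimeSeries, epoch_s: float = 2.5
) -> tuple[float, float]:
    """(STV, LTV) from 2.5-s epoch averages, minute-wise.

    STV: mean over minutes of the mean absolute successive difference of the
    epoch averages within the minute.  LTV: mean over minutes of the range
    (max - min) of the epoch averages.  Requires >= 2 minutes of signal.
    """
    x = series.require_complete("STV/LTV")
    fs = series.fs
    if x.size < 2 * 60 * fs:
        raise ValueError("STV/LTV need at least 2 minutes of signal")
    epochs = _epoch_averages(x, fs, epoch_s)
    per_min = int(round(60.0 / epoch_s))
    n_min = epochs.size // per_min
    stvs, ltvs = [], []
    for i in range(n_min):
        e = epochs[i * per_min : (i + 1) * per_min]
        stvs.append(np.mean(np.abs(np.diff(e))))
        ltvs.append(e.max() - e.min())
    return float(np.mean(stvs)), float(np.mean(ltvs))


def band_energies(series: TimeSeries, window_s: float = 120.0) -> Dict[str, float]:
    """Energies of the Welch periodogram integrated over the four CTG bands.

    50%-overlapping windows (default 2 min at 4 Hz); band edges are treated
    as half-open intervals so the bands plus the out-of-band remainder
    partition the total power exactly.
    """
    x = series.require_complete("band energies")
    fs = series.fs
    nperseg = min(int(round(window_s * fs)), x.size)
    f, pxx = signal.welch(x - x.mean(), fs=fs, nperseg=nperseg)
    df = f[1] - f[0] if f.size > 1 else 1.0
    out = {}
    top = max(hi for _, hi in BANDS.values())
    for name, (lo, hi) in BANDS.items():
        # half-open bands partition the axis; the topmost includes Nyquist
        m = (f >= lo) & ((f <= hi) if hi == top else (f < hi))
        out[name] = float(np.sum(pxx[m]) * df)
    out["total"] = float(np.sum(pxx) * df)
    mf_hf = out["mf"] + out["hf"]
    out["lf_mf_hf_ratio"] = float(out["lf"] / mf_hf) if mf_hf > 0 else np.inf
    return out


def _phi_counts(x: np.ndarray, m: int, r: float, self_match: bool) -> np.ndarray:
    """Per-template fraction of templates within Chebyshev distance r."""
    n = x.size - m + 1
    templ = np.lib.stride_tricks.sliding_window_view(x, m)
    D = cdist(templ, templ, "chebyshev")
    within = D <= r
    if not self_match:
        np.fill_diagonal(within, False)
        denom = n - 1
    else:
        denom = n
    return within.sum(axis=1) / denom


def approximate_entropy(series, m: int = 2, r: Optional[float] = None) -> float:
    """Approximate entropy ApEn(m, r); default r = 0.2 x SD (0 for constants)."""
    x = as_series(series).require_complete("ApEn")
    if np.std(x) == 0:
        return 0.0
    r = 0.2 * np.std(x) if r is None else r
    phi = []
    for mm in (m, m + 1):
        c = _phi_counts(x, mm, r, self_match=True)
        phi.append(np.mean(np.log(c)))
    return float(phi[0] - phi[1])


def sample_entropy(series, m: int = 2, r: Optional[float] = None) -> float:
    """Sample entropy SampEn(m, r), self-matches excluded; 0 for constants."""
    x = as_series(series).require_complete("SampEn")
    if np.std(x) == 0:
        return 0.0
    r = 0.2 * np.std(x) if r is None else r
    # count template pairs at length m and m+1 over the same n-m templates
    n = x.size
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[: n - m]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    B = np.sum(cdist(tm, tm, "chebyshev") <= r) - tm.shape[0]
    A = np.sum(cdist(tm1, tm1, "chebyshev") <= r) - tm1.shape[0]
    if B == 0:
        return np.inf
    if A == 0:
        return np.inf
    return float(-np.log(A / B))


def baseline_features(fhr, config: Optional[FeatureConfig] = None) -> Dict[str, float]:
    """Conventional FHR feature set (everything except the Hausdorff feature)."""
    cfg = config or FeatureConfig()
    ts = as_series(fhr)
    stv, ltv = short_long_term_variability(ts, epoch_s=cfg.epoch_s)
    bands = band_energies(ts, window_s=cfg.welch_window_s)
    feats = {
        "stv": stv,
        "ltv": ltv,
        "vlf": bands["vlf"],
        "lf": bands["lf"],
        "mf": bands["mf"],
        "hf": bands["hf"],
        "lf_mf_hf_ratio": bands["lf_mf_hf_ratio"],
        "apen": approximate_entropy(ts, m=cfg.entropy_m),
        "sampen": sample_entropy(ts, m=cfg.entropy_m),
    }
    return feats


def feature_ph_correlation(features: pd.DataFrame, ph: np.ndarray) -> pd.DataFrame:
    """Pearson correlation matrix over the feature columns plus pH.

    Requires >= 3 records and no missing entries; constant columns have no
    defined correlation and raise.
    """
    df = features.copy()
    df["ph"] = np.asarray(ph, dtype=float)
    if len(df) < 3:
        raise ValueError("need at least 3 records for a correlation matrix")
    if df.isna().any().any():
        raise ValueError("feature table contains missing entries")
    constant = [c for c in df.columns if df[c].std() == 0]
    if constant:
        raise ValueError(f"correlation undefined for constant column(s): {constant}")
    return df.corr(method="pearson")
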