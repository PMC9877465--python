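"""Synthetic-data generators for every fixture the package needs.

* :func:`simulate_lorenz` — the Lorenz system

      dx/dt = a (y - x),  dy/dt = x (c - z) - y,  dz/dt = x y - b z

  at the classic chaotic parameter values a=10, b=8/3, c=28, integrated with
  fixed-step RK4 and observed through its X-projection.  Default sampling
  interval of the *observed* series is 0.05 time units (the integrator runs
  at dt=0.01 and every 5th state is recorded) so that a one-sample delay is a
  dynamically meaningful lag for delay embedding.
* :func:`simulate_coupled_maps` — unidirectionally coupled logistic maps
  (x drives y), the standard ground-truth benchmark for convergent cross
  mapping.
* :func:`simulate_ctg` — CTG-like paired series in which uterine activity
  causally drives fetal heart rate: UA is baseline tone plus Gaussian-bump
  contractions at Poisson onsets; FHR is a baseline plus stationary
  Matern-3/2 variability, a lagged negative (deceleration) response to UA,
  and white observation noise.  The shapes and rates are this package's own
  calibration, chosen to be visually and spectrally CTG-like; they encode
  the causal arrow UA -> FHR but make no claim of pathophysiological realism.
* :func:`make_mask` — random or burst missingness masks.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .series import TimeSeries

__all__ = [
    "LorenzConfig",
    "SyntheticCTGConfig",
    "simulate_lorenz",
    "simulate_coupled_maps",
    "simulate_ctg",
    "make_mask",
]


@dataclass
class LorenzConfig:
    a: float = 10.0
    b: float = 8.0 / 3.0
    c: float = 28.0
    initial_state: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    dt: float = 0.01            # RK4 integration step (time units)
    duration: float = 75.0      # retained trajectory length after burn-in
    burn_in: float = 100.0      # discarded transient
    observe_every: int = 5      # record every k-th step: sample interval k*dt

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("step size must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive after burn-in")
        if self.observe_every < 1:
            raise ValueError("observe_every must be >= 1")


def _lorenz_rhs(state: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    x, y, z = state
    return np.array([a * (y - x), x * (c - z) - y, x * y - b * z])


def simulate_lorenz(
    config: Optional[LorenzConfig] = None, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Integrate the Lorenz system with fixed-step RK4.

    Returns ``(trajectory, x_projection)``: the retained 3-D states of shape
    (n, 3) at the observation interval, and the X-coordinate series X(t).
    The seed only perturbs the initial state (1e-6 jitter) so replicates
    explore different stretches of the attractor; seed=0 keeps the configured
    initial state exactly.
    """
    cfg = config or LorenzConfig()
    state = np.asarray(cfg.initial_state, dtype=float)
    if seed != 0:
        state = state + 1e-6 * np.random.default_rng(seed).standard_normal(3)
    n_burn = int(round(cfg.burn_in / cfg.dt))
    n_keep = int(round(cfg.duration / cfg.dt))
    traj = []
    for i in range(n_burn + n_keep):
        k1 = _lorenz_rhs(state, cfg.a, cfg.b, cfg.c)
        k2 = _lorenz_rhs(state + 0.5 * cfg.dt * k1, cfg.a, cfg.b, cfg.c)
        k3 = _lorenz_rhs(state + 0.5 * cfg.dt * k2, cfg.a, cfg.b, cfg.c)
        k4 = _lorenz_rhs(state + cfg.dt * k3, cfg.a, cfg.b, cfg.c)
        state = state + (cfg.dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError("Lorenz integration blew up (non-finite state)")
        # record at integer multiples of the observation interval
        if i + 1 > n_burn and (i + 1 - n_burn) % cfg.observe_every == 0:
            traj.append(state.copy())
    traj = np.array(traj)
    return traj, traj[:, 0].copy()


BETA_MAX = 0.33  # maximal forcing coefficient keeping the driven map in (0, 1)


def simulate_coupled_maps(
    coupling: float,
    length: int = 1000,
    seed: int = 0,
    r_x: float = 3.8,
    r_y: float = 3.65,
    burn_in: int = 200,
) -> Tuple[np.ndarray, np.ndarray]:
    """Unidirectionally coupled logistic maps: x autonomous, x drives y.

        x[t+1] = x[t] (r_x - r_x x[t])
        y[t+1] = y[t] (r_y - r_y y[t] - beta x[t]),   beta = coupling * 0.33

    ``coupling`` is a dimensionless knob in [0, 1): the fraction of the
    maximal forcing coefficient (0.33) for which the driven map provably
    stays inside (0, 1) at r_y = 3.65 — a raw coefficient above that bound
    escapes the unit interval, so the full [0, 1) knob range is usable.

    The causal arrow is x -> y only.  r_y sits in the chaotic band so the
    driven map keeps a positive conditional Lyapunov exponent under
    forcing: y retains internal state that the autonomous x never encodes,
    which is what makes the arrow detectable as unidirectional (a periodic
    choice such as r_y = 3.5 generalized-synchronizes to x, after which
    the reverse cross-mapping spuriously succeeds; the same masquerade
    appears when the forcing approaches the boundedness limit).
    """
    if not 0 <= coupling < 1:
        raise ValueError("coupling must be in [0, 1)")
    beta = coupling * BETA_MAX
    rng = np.random.default_rng(seed)
    x = float(rng.uniform(0.2, 0.8))
    y = float(rng.uniform(0.2, 0.8))
    xs = np.empty(length)
    ys = np.empty(length)
    for t in range(burn_in + length):
        x_new = x * (r_x - r_x * x)
        y_new = y * (r_y - r_y * y - beta * x)
        x, y = x_new, y_new
        if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
            raise ValueError(
                f"coupled-map trajectory left [0,1] at step {t} "
                f"(x={x:.3f}, y={y:.3f}); reduce coupling or map rates"
            )
        if t >= burn_in:
            xs[t - burn_in] = x
            ys[t - burn_in] = y
    return xs, ys


@dataclass
class SyntheticCTGConfig:
    duration_min: float = 10.0
    fs: float = 4.0
    baseline_bpm: float = 140.0
    variability_sd_bpm: float = 6.0        # Matern-3/2 FHR variability amplitude
    variability_lengthscale_s: float = 4.0
    contraction_rate_per_10min: float = 4.0
    contraction_width_s: float = 25.0      # Gaussian bump SD
    ua_tone: float = 10.0                  # resting tone, arbitrary units
    ua_amplitude: float = 50.0             # contraction peak above tone
    deceleration_gain_bpm: float = 20.0    # FHR drop per unit normalized UA bump
    deceleration_lag_s: float = 15.0
    noise_sd_bpm: float = 2.0
    ua_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        for name in (
            "contraction_rate_per_10min",
            "deceleration_gain_bpm",
            "noise_sd_bpm",
            "variability_sd_bpm",
            "ua_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _matern32_cov(lags_s: np.ndarray, sd: float, ell: float) -> np.ndarray:
    r = np.sqrt(3.0) * np.abs(lags_s) / ell
    return sd**2 * (1.0 + r) * np.exp(-r)


def _sample_stationary_gp(
    n: int, fs: float, sd: float, ell: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample a stationary Matern-3/2 GP on a regular grid by circulant embedding."""
    if sd == 0:
        return np.zeros(n)
    m = 1
    while m < 2 * n:
        m *= 2
    lags = np.minimum(np.arange(m), m - np.arange(m)) / fs
    c = _matern32_cov(lags, sd, ell)
    lam = np.fft.rfft(c).real
    lam = np.maximum(lam, 0.0)  # clip tiny negative eigenvalues of the embedding
    z = rng.standard_normal(m // 2 + 1) + 1j * rng.standard_normal(m // 2 + 1)
    z[0] = z[0].real * np.sqrt(2)
    z[-1] = z[-1].real * np.sqrt(2)
    f = np.fft.irfft(z * np.sqrt(lam * m / 2.0), n=m)
    return f[:n]


def simulate_ctg(
    config: Optional[SyntheticCTGConfig] = None, seed: int = 0
) -> Tuple[TimeSeries, TimeSeries]:
    """Generate a causally coupled (UA -> FHR) synthetic CTG pair.

    Independent RNG streams are spawned per component (contractions,
    variability, observation noise), so changing the deceleration gain leaves
    the UA channel bit-identical.
    """
    cfg = config or SyntheticCTGConfig()
    ss = np.random.SeedSequence(seed)
    rng_ua, rng_var, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    n = int(round(cfg.duration_min * 60 * cfg.fs))
    t = np.arange(n) / cfg.fs  # seconds

    # --- uterine activity: Poisson contraction onsets, Gaussian bumps ----
    rate_per_s = cfg.contraction_rate_per_10min / 600.0
    drive = np.zeros(n)  # normalized contraction drive, unit peak per bump
    t_next = rng_ua.exponential(1.0 / rate_per_s) if rate_per_s > 0 else np.inf
    onsets = []
    while t_next < t[-1]:
        onsets.append(t_next)
        t_next += rng_ua.exponential(1.0 / rate_per_s)
    for onset in onsets:
        amp = rng_ua.uniform(0.6, 1.0)
        drive += amp * np.exp(-0.5 * ((t - onset) / cfg.contraction_width_s) ** 2)
    ua_vals = (
        cfg.ua_tone
        + cfg.ua_amplitude * drive
        + cfg.ua_noise_sd * rng_ua.standard_normal(n)
    )

    # --- fetal heart rate -------------------------------------------------
    variability = _sample_stationary_gp(
        n, cfg.fs, cfg.variability_sd_bpm, cfg.variability_lengthscale_s, rng_var
    )
    lag_samples = int(round(cfg.deceleration_lag_s * cfg.fs))
    lagged_drive = np.zeros(n)
    if lag_samples < n:
        lagged_drive[lag_samples:] = drive[: n - lag_samples]
    fhr_vals = (
        cfg.baseline_bpm
        + variability
        - cfg.deceleration_gain_bpm * lagged_drive
        + cfg.noise_sd_bpm * rng_noise.standard_normal(n)
    )

    fhr = TimeSeries(fhr_vals, fs=cfg.fs, name="fhr_bpm")
    ua = TimeSeries(ua_vals, fs=cfg.fs, name="ua")
    return fhr, ua


def make_mask(
    length: int,
    fraction: Optional[float] = None,
    bursts: Optional[Tuple[int, int]] = None,
    seed: int = 0,
) -> np.ndarray:
    """Boolean missingness mask: True marks a missing sample.

    Exactly one of ``fraction`` (uniform random, exactly
    ``floor(fraction*length)`` missing) or ``bursts`` (``(n_bursts,
    burst_length)`` non-overlapping contiguous runs) must be given.
    """
    if (fraction is None) == (bursts is None):
        raise ValueError("specify exactly one of fraction or bursts")
    rng = np.random.default_rng(seed)
    mask = np.zeros(length, dtype=bool)
    if fraction is not None:
        if not 0 <= fraction < 1:
            raise ValueError("fraction must be in [0, 1)")
        k = int(np.floor(fraction * length))
        if k > 0:
            mask[rng.choice(length, size=k, replace=False)] = True
        return mask
    n_bursts, burst_len = bursts
    if n_bursts < 0 or burst_len <= 0:
        raise ValueError("burst spec must be (n_bursts >= 0, burst_length > 0)")
    if n_bursts * burst_len > length:
        raise ValueError("burst spec does not fit in the series")
    placed = 0
    attempts = 0
    starts: list[int] = []
    while placed < n_bursts:
        attempts += 1
        if attempts > 10000:
            raise ValueError("could not place non-overlapping bursts; spec too dense")
        start = int(rng.integers(0, length - burst_len + 1))
        if any(abs(start - s) < burst_len for s in starts):
            continue
        starts.append(start)
        mask[start : start + burst_len] = True
        placed += 1
    return mask
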