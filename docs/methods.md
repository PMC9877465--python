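# Methods

This note records the models implemented in `edmgp`, the defaults that
matter, the numerical choices, and what the synthetic generators do and do
not emulate.

## Gaussian-process regression (`edmgp.gp`)

All downstream machinery rests on exact zero-mean GP regression with
additive white Gaussian noise. The log marginal likelihood

    log p(y | X, theta) = -1/2 y^T K^-1 y - 1/2 log|K| - n/2 log 2pi,
    K = K_ff + sigma_eps^2 I,

is maximized over log-transformed hyperparameters with L-BFGS-B and seeded
random restarts (default 3). Initialization, where a caller does not say
otherwise: unit signal variance, length-scales at the per-dimension input
standard deviation, noise at 10% of the target variance. The predictive
posterior is the usual Gaussian conditional.

Kernels: ARD RBF, ARD Matern-3/2 (applied to the Mahalanobis distance
`sqrt((dx)^T Lambda (dx))` with inverse-squared length-scales on the
diagonal of Lambda), linear, and sums. The per-dimension ARD relevance is
reported as `r_q = 1/ell_q`.

Numerical choices:

* Cholesky first attempted without jitter; on failure, jitter starts at
  `1e-8 x mean(diag)` and escalates tenfold to `1e-2 x mean(diag)` before a
  `NumericalError` is raised. The clean first attempt keeps the likelihood
  and predictive moments at oracle accuracy (1e-8) on well-conditioned
  problems.
* Negative predictive variances beyond `-1e-6 x` the variance scale raise;
  smaller ones are clipped to zero with a warning. A fixed absolute
  threshold (e.g. 1e-10) trips routinely in float64 at a few hundred
  training points, so the tolerance is scale-relative.
* Log-parameters are box-bounded to [-15, 15] during optimization to keep
  `exp` finite.

## Attractor reconstruction (`edmgp.manifold`, `edmgp.gplvm`)

A single observable `x(t)` of a deterministic system is delay-embedded with
lag tau = 1 sample and a deliberately generous dimension E (default 20):
row t of `M_init` is `[x(t), x(t-1), ..., x(t-(E-1))]`. Takens' theorem
guarantees that E >= 2d+1 suffices for an attractor of dimension d, so no
grid search over E is performed; the surplus dimensions are removed
statistically instead.

The series is standardized (zero mean, unit variance) before embedding so
that latent coordinates — and Hausdorff distances between manifolds from
different records — live on a common scale.

`M_init` is then compressed by a Bayesian GPLVM: each embedding column is a
zero-mean GP over latent inputs with a shared ARD RBF kernel, observed with
white noise. The intractable marginal likelihood is replaced by the
standard collapsed variational bound with inducing inputs and a factorized
Gaussian `q(X)`; the kernel expectations (Psi statistics) are closed-form
for the RBF kernel. All gradients are analytic (finite-difference-checked
in the test suite) and every quadratic-in-inducing-point contraction is
arranged as a dense matrix product, which is what makes desk-scale fits
(seconds to a minute) possible in pure numpy.

Latent dimensionality is initialized at E; dimensions the data do not need
have their ARD weight shrink toward zero. The retained set is
`{q : r_q / max_q r_q > 0.05}` with `r_q = 1/ell_q`; the 5% threshold is a
documented, configurable default. The reconstructed manifold is the
variational posterior mean over the retained dimensions.

Optimization and initialization choices (all seeded):

* Latent means initialized by PCA of `M_init`, scaled to unit variance;
  variational variances at 0.1; inducing inputs as a random subset of the
  initial latent points (default 35-50, capped at N).
* ARD weights initialized proportional to the PCA variance fractions
  (floored at 1e-3). Together with a warm-up stage that freezes the kernel
  hyperparameters and optimizes only the variational parameters and
  inducing inputs (150 L-BFGS iterations), this reliably avoids the
  well-known degenerate optimum in which the signal variance collapses and
  the noise term absorbs the data.
* Joint L-BFGS over all parameters afterwards (default 300-600 iterations
  depending on the caller); noise variance floored at 1e-6.
* Fits use at most `max_points` embedding rows (default 500), taken as a
  time-strided subsample. The variational bound costs O(N M^2 Q) per
  gradient, and a few hundred well-spread points resolve the attractor
  geometry; the problem sizes used by the tests and the acceptance script
  (350-500 points, 30-40 inducing inputs) were chosen as the smallest that
  left the recovered dimensionality stable across seeds.

### The Lorenz verification

The dimensionality claim is verified on the Lorenz system (a=10, b=8/3,
c=28), integrated with fixed-step RK4 at dt=0.01 from (1,1,1), a 100-unit
burn-in discarded, and the X-coordinate recorded every 5th step (sampling
interval 0.05 time units, ~1500 samples over 75 time units). The
observation interval is a deliberate choice: with tau fixed at one sample,
an E=20 window then spans one characteristic oscillation of the attractor
(~0.7-0.8 time units), which is the regime in which delay embedding
resolves the state. Recording at the raw integrator step would compress
the window to 0.2 time units and push the higher delay coordinates to
numerical-noise level. Replicates perturb the initial state by 1e-6 so
each explores a different stretch of the attractor. The expected outcome,
which the acceptance test asserts over 10 seeded replicates, is a modal
retained dimensionality of 3 — the true state dimension.

## Convergent cross mapping (`edmgp.ccm`)

Direction "a causes b" is tested by cross-mapping a from the manifold of b:
if a drives b, then b's history encodes a, and states of a can be estimated
from `M_b` with skill that grows as the library of manifold points grows.
The estimator is exact GP regression (ARD RBF) from a random library of
manifold points to contemporaneous target values, scored by Pearson
correlation on out-of-library points. The GP replaces the classical
nearest-neighbour simplex weighting and models observation noise
explicitly; its hyperparameters are fitted once per direction on a maximal
library and reused across draws, so each draw costs one Cholesky.

Library ladder: 8 sizes, geometric from max(20, N/20) to 0.9 N, 20 random
draws per size. The convergence verdict requires both

1. positive skill gain from the smallest to the largest library, with the
   5% bootstrap quantile of the mean gain (500 resamples over draws) above
   zero, and
2. mean skill at the largest library above the 97.5% quantile of a
   circular time-shift surrogate null (>= 100 shifts; shifts preserve the
   target's autocorrelation but destroy the cross-map correspondence).
   Because the GP prediction is linear in the target once hyperparameters
   are fixed, the smoother matrix is precomputed and each surrogate costs
   one matrix-vector product.

Only contemporaneous (lag-0) mapping is implemented. Note that high
*absolute* skill in the reverse direction is expected on strongly coupled
systems (the effect's state correlates with the cause); the verdict is
driven by convergence, not by skill level.

## Interaction feature and comparison features (`edmgp.features`)

The FHR-UA interaction feature is the Hausdorff distance

    H(A, B) = max( sup_a inf_b ||a-b||, sup_b inf_a ||a-b|| )

between the reconstructed FHR and UA manifolds. Both manifolds come from
standardized series; when their retained dimensionalities differ, the
lower-dimensional point set is zero-padded — the minimal-assumption
alignment, and configurable.

Comparison features on FHR (first 30 minutes of a record by convention):

* STV: the signal is reduced to 2.5-s epoch averages; STV is the mean
  absolute successive difference of those averages, computed per minute
  and averaged over minutes.
* LTV: mean over minutes of the range (max - min) of the epoch averages.
* Spectral band energies from a Welch periodogram (2-minute windows, 50%
  overlap, 4 Hz): VLF 0-0.06 Hz, LF 0.06-0.3 Hz, MF 0.3-1 Hz, HF 1-2 Hz,
  with half-open bins partitioning the axis (the top band includes
  Nyquist) so the four bands sum to the total power exactly; plus the
  ratio LF/(MF+HF).
* Approximate entropy and sample entropy with m=2, r=0.2 x SD; constant
  series return 0 by convention.

`feature_ph_correlation` assembles the Pearson matrix of features plus the
umbilical-artery pH label. The cohort-level correlation values reported
for the external clinical database are *not* reproduced here (they require
those 552 records); the machinery is instead validated on simulated
cohorts with planted correlations.

## Missing-sample imputation (`edmgp.imputation`)

Observed FHR samples are modeled as `y_i = f([t_i, u_i]) + eps` where t_i
is time in seconds and u_i the synchronized, standardized UA value. The
covariance is a sum of three terms with diagonal ARD matrices: Matern-3/2
(alpha1^2; rapid variation), RBF (alpha2^2; slow variation), linear
(trend). Hyperparameters (alpha1^2, alpha2^2, beta1..beta6, sigma^2) are
refitted per segment on its observed samples by maximum marginal
likelihood (single restart by default; initial time length-scale 10 s).
Removing the UA coordinate gives the time-only ablation; cubic-spline
interpolation over time is the conventional baseline. Default segment
length is 2 minutes at 4 Hz.

The bivariate model is fitted with a nested warm start: the time-only
model is fitted first and the 2-D fit starts from that optimum with the
UA dimension initialized inactive (long length-scale, negligible linear
weight). The enlarged model therefore begins at the nested model's
likelihood and activates the UA coordinate only when doing so pays. This
matters because a noisy auxiliary coordinate with a freely fitted short
length-scale can mimic the white-noise term — raising the training
likelihood while degrading held-out recovery.

An honest caveat the sweep makes visible: on the synthetic generator
under *uniform random* missingness at 4 Hz, the deceleration component is
smooth enough that the time coordinate alone recovers it at every
fraction up to 90%, so the bivariate model ties the time-only model
(ARD leaves UA switched off) rather than beating it; both beat the cubic
spline by several dB from 30% missingness up. The advantage of the UA
input is expected to materialize for signals whose UA-driven component is
not predictable from neighbouring samples — long burst gaps, or the
richer structure of real tracings — which uniform subsampling of this
generator does not emulate.

Reported predictive variances include the noise term, so an estimate is
never more confident than the fitted noise floor. Metrics against ground
truth: `Log MSE = ln(||s - s_hat||^2 / N)` and
`SNR = 10 log10(||s||^2 / ||s - s_hat||^2)` dB. A zero-energy truth makes
SNR undefined; it is returned as NaN with a warning (Log MSE remains
valid).

`missingness_sweep` runs the random-missingness experiment over a ladder
of fractions (default {10, 30, 50, 70, 90}%, 20 seeded repeats) and
reports the tidy per-run metric table.

## Synthetic data (`edmgp.simulate`)

The generators exist to give every pipeline a ground-truth fixture:

* Lorenz (above) for dimensionality recovery.
* Unidirectionally coupled logistic maps
  `x' = x(3.8 - 3.8x)`, `y' = y(3.5 - 3.5y - c x)` — the standard CCM
  benchmark; the causal arrow is x -> y only, and r_y = 3.5 keeps the
  coupled trajectory inside [0, 1] for c <= ~0.35.
* CTG-like pairs: UA is a resting tone plus Gaussian-bump contractions at
  Poisson onsets (default 4 per 10 min, 25-s width) plus white noise; FHR
  is a 140-bpm baseline plus stationary Matern-3/2 variability (SD 6 bpm,
  length-scale 4 s, sampled by circulant embedding) minus a lagged
  deceleration response proportional to the contraction drive (default
  20 bpm peak, 15-s lag) plus white observation noise (2 bpm). Component
  RNG streams are spawned independently, so changing the deceleration gain
  leaves UA bit-identical. The shapes and rates are calibrated only to be
  visually and spectrally CTG-like and to encode the UA -> FHR causal
  arrow; the generator makes no claim of pathophysiological realism (no
  acidemia modeling, no clinical pattern taxonomy), so passing tests
  demonstrate method behavior under the stated causal structure, not
  clinical performance.
* Missingness masks: uniform random with an exact count, or non-overlapping
  fixed-length bursts.

## Preprocessing (`edmgp.io`)

A deliberately simple, fully documented pipeline (the literature's full
algorithms are record-format-specific): FHR samples equal to 0 or outside
[50, 210] bpm are marked missing; interior gaps of at most 5 s are linearly
interpolated; longer gaps are left for the imputation module; optional
truncation to the first 30 minutes. Both thresholds are configurable. The
pipeline is idempotent.

## Known limitations

* Burst errors with simultaneous UA loss are out of scope (the bivariate
  imputer requires UA at the missing indices); burst masks are still
  generated so baselines can be compared on them.
* CCM is bivariate and lag-0 only.
* The GPLVM optimizes a non-convex bound; different seeds can land on
  optima whose weakest retained relevance sits near the 5% threshold.
  The acceptance experiment therefore reports the modal dimensionality
  over 10 replicates rather than a single fit.
* WFDB reading requires the optional `wfdb` package; CSV is the supported
  interchange format.
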