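# Methods

## Model

Log2-transformed optical density is modeled as a zero-mean Gaussian
process with independent Gaussian observation noise:

    y(x) = f(x) + ε,   ε ~ N(0, σ²_nugget),
    f ~ GP(0, κ),
    κ(x, x') = σ²_RBF · exp(−‖x − x'‖² / ℓ²).

Note the squared-exponential convention used throughout this package has
no ½ factor and puts ℓ² in the denominator.  This is a pure
reparameterization of the lengthscale relative to the textbook form
`exp(−d²/2ℓ²)`; a fitted ℓ here equals √2 times the textbook ℓ.  The
Matérn-3/2 kernel uses the standard scaled distance r = ‖x − x'‖/ℓ, and
the ARD (automatic relevance determination) kernel is the standard
per-dimension squared exponential `σ²·exp(−Σ_k Δ_k²/ℓ_k²)`.

Hyperparameters (variance, lengthscales, nugget) are set by type-II
maximum likelihood: L-BFGS-B on log-parameters with analytic gradients,
lengthscale bounds [1e-2, 1e3] in input units, nugget floor 1e-10, and
jitter escalation 1e-10 → 1e-4 on Cholesky failure.  Random restarts
perturb the initialization in log space; fits are deterministic given a
seed.  Initial lengthscales are a quarter of the input span for
continuous dimensions and 1.0 for binary-like dimensions (≤3 distinct
values).  The binary case matters: starting a {0,1} covariate at
span/4 = 0.25 makes the cross-level correlation exp(−1/0.25²) ≈ 1e-7, a
saturated regime where the gradient vanishes and the optimizer cannot
learn whether the covariate is relevant.

### Nugget semantics

The printed single-pair kernels carry the noise term as
`σ²_nugget·1[x_i = x_j]`.  In the training covariance the nugget is
added per *observation index* (`K + σ²I`), not per coincident input
value: replicate wells measured at the same time share an input but have
independent noise.  The scalar kernel functions keep the indicator form.

## Growth parameters

Because the squared-exponential kernel is infinitely differentiable, the
time derivative of the latent function is itself a GP.  The cross- and
auto-covariances of (d/dt)f are the exact first and second mixed partial
derivatives of the implemented kernel,

    ∂κ/∂t   = −2(t−t')/ℓ² · κ,
    ∂²κ/∂t∂t' = (2/ℓ²)(1 − 2(t−t')²/ℓ²) · κ,

derived analytically rather than transcribed, and verified in the test
suite against central finite differences (mean) and the Monte-Carlo
covariance of differentiated joint posterior samples (10⁴ draws, 3 MC
standard errors).

* **μ_max** — the maximum of the derivative posterior mean over a
  100-point grid spanning the observed time range (units: log2-OD/h).
* **A (carrying capacity)** — the maximum of the noiseless latent
  posterior mean over the same grid (log2-OD units).
* **AUC (growth potential)** — the left-Riemann linear functional
  a = (Δt, …, Δt) applied to the noiseless posterior on a 50-point even
  grid, giving AUC ~ N(a·μ, aΣaᵀ) exactly.  No trapezoid correction is
  applied; with 50 points on smooth fits the discretization error is
  under 2%.

Credible intervals for the two max-type statistics come from the 2.5/97.5
percentiles of per-sample maxima across 10⁴ joint posterior draws
(seeded; eigendecomposition sampling with negative eigenvalues clipped at
zero).  A pointwise alternative (the marginal at the argmax) is available
via `method="pointwise"`; the max-over-samples construction is the
default because the grid maximum is a functional of the whole curve, not
of one point.  On near-degenerate (noiseless) posteriors the percentile
band can exclude the point estimate by Monte-Carlo jitter of order 1e-6;
the interval is widened to always contain the point.

## Primary models and the benchmark

Gompertz, population logistic, Schnute and Richards curves are
implemented in their standard microbiological parameterizations (shared
parameters: carrying capacity A, maximum growth rate μ_max, lag λ;
Schnute adds shapes a, b; Richards adds v, reducing to the logistic at
v = 1; Gompertz is the a > 0, b → 0 limit of Schnute).  Parameters are
estimated by damped least squares (Levenberg–Marquardt via
`scipy.optimize.curve_fit`), with heuristic initialization (A = max y,
μ_max = max finite-difference slope, λ = its location).  Non-convergence
is reported as a flag, never an exception, so a benchmark can score
hundreds of curves; unconverged fits are recorded as missing rather than
infinite MSE, with counts in the summary.

The benchmark splits each curve 80/20 at the record level, fits every
model on the training portion, and scores mean squared error on the
held-out portion (GP prediction = posterior mean).  GP-vs-model
comparisons use a one-sided Welch t-test; Welch because equal variances
cannot be assumed between model families.  Family-wise control across
per-strain parameter tests is by the Bonferroni bound (`bonferroni`),
the simplest procedure consistent with an FWER budget.

## Differential testing

The approximate Bayes factor between nested covariate designs is the
difference of their maximized log marginal likelihoods (point-estimated
hyperparameters; no integration over hyperparameter uncertainty).  The
strain test compares f(time) against f(time, strain); the stress test
compares f(time, strain, stress) against the same design plus the
strain×stress interaction, which is always recomputed as the product of
the encoded columns, never read from input.

Significance is calibrated by permutation: within each time point (and
within each stress arm for the stress test, preserving the stress
distribution), strain labels are shuffled across observations, so the
per-time-point label counts are exactly preserved.  With 100
permutations, a real score exceeding the 80th percentile of permuted
scores corresponds to FDR ≤ 20%; the empirical FDR at threshold c is
`|{perm > c}| / (|{real > c}| · n_perm)`, the single real test counted at
the permutation scale.  Ties at the threshold are not significant
(strict inequality).  For the strain test the null design involves only
time, so its marginal likelihood is computed once and reused across
permutations — an exact saving, not an approximation.

Whether the stress-test permutation should shuffle labels across both
stress arms jointly is genuinely open; this implementation restricts the
shuffle within arms (configurable via `within`), which preserves the
marginal design exactly.

### Posterior contrasts

The per-time-point difference between two latent growth functions
(mutant vs parent, or interaction-on vs interaction-off for the stress
phenotype) is an exact linear functional of the joint noiseless
posterior: for the quadruple (f_on(t_k), f_on(t₀), f_off(t_k),
f_off(t₀)), the contrast a = [1, −1, −1, 1] subtracts the t₀ difference,
so the series is exactly zero at t₀ and corrects for pre-existing
baseline offsets.  The t₀ correction is applied uniformly in both
contrast modes.  A time point is flagged when the central 95% normal
interval excludes zero.

### Hierarchical (cross-study) model

Batches share a growth function g with per-batch deviations f_b:

    Cov(y_b(x), y_b'(x')) = K_g(x, x') + 1[b = b']·K_f(x, x') + σ²·1[same obs].

This additive two-level kernel is the exact finite-batch marginal of the
nested-GP construction and avoids iterative mean-function passing.  With
only two batches the unconstrained model is poorly identified: type-II
ML happily sets K_g ≈ 0 and re-explains the shared trend twice with a
*smoother* independent K_f, because a longer-lengthscale process has
fewer effective degrees of freedom and assigns the broad sigmoid trend
higher density.  The implementation therefore ties the batch kernel to
the shared kernel — K_f = ρ·K_g with the same ARD lengthscales and a
ratio ρ ∈ (0, 1] — so the batch level can only carry deviations around
the shared function, never replace it.  Under this constraint the
shared-function posterior recovers an offset-free truth to within ±0.06
when two batches carry opposite ±0.4 smooth offsets (the test suite
asserts ±0.15), and with zero batch effect ρ → 0 reproduces the pooled
single-level fit.

The cross-study interaction test scores the hierarchical marginal
likelihood with and without the interaction column and permutes strain
labels within (batch, time point, stress arm).

### Enrichment

Over-representation of a strain class among significant hits is the
upper-tail hypergeometric probability P(X ≥ k) via `scipy.stats.hypergeom`.

## Synthetic data

The generator emulates a 48-h plate-reader experiment sampled every
30 min with 12 replicates per (strain, condition) arm: log2-OD follows a
Gompertz curve (defaults A = 2.0 log2 units, μ_max = 0.3/h, λ = 5 h —
a realistic halophile-scale trajectory) plus IID Gaussian noise
(σ = 0.05 log2 units).  Effects act multiplicatively on (A, μ_max)
and/or as additive log2 offsets that saturate over ~4 h after
inoculation.  The stress regime adds a negative linear ramp after a
configurable onset (default 0.08 log2/h after 24 h), the simplest shape
reproducing the grow-peak-decline pattern of severe oxidative stress —
and the shape that defeats sigmoid models.  Batch offsets are smooth:
GP draws (lengthscale 12 h, amplitude 0.3, anchored at zero at t = 0) or
fixed sinusoids for exactly-opposite-offset scenarios.

What the generator does *not* emulate: heteroscedastic or time-varying
noise, replicate-level random effects, instrument artifacts in the first
time points, non-Gompertz baseline shapes, and continuous dose
responses.  Passing tests therefore demonstrate correctness of the
inference machinery under the stated generative assumptions, not
robustness to every failure mode of real plate-reader data.

## Preprocessing conventions

Raw OD is log2-transformed and the starting level subtracted in log
space: per (strain, condition[, batch]) group, a degree-5 polynomial is
least-squares fit to all raw points at the first 10 distinct time points
(pooling replicates), and its value at t = 0 is subtracted from the
whole group, so every group starts at ≈0.  Pooling raw points rather
than replicate means weights time points by their replication, which is
the natural least-squares choice.  Subsampling to a coarser grid keeps
records whose time is within 1e-6 h of a multiple of the interval
(plate readers emit near-exact grids).  Train/test splitting is at the
record level within each curve, seeded.

## Validation problem sizes

The acceptance suite (scripts/acceptance.py and the mirror tests) uses
scaled study sizes chosen to exercise each claim: calibration runs 50
null datasets (6 replicates/arm) and 50 effect datasets (50% μ_max
reduction, 12 replicates/arm) on a 6-h grid with 100 permutations each;
the stress-regime benchmark uses 20 single-replicate curves at 1-h
resolution; the batch study uses 2 batches × 6 replicates at 2-h
resolution for recovery and 3 seeded repeats of the masked-interaction
scenario (interaction μ-scale 0.85 against ±0.4 offsets, 20
permutations).  Permutation fits use a single optimizer start with the
data-driven initialization, applied identically to real and permuted
data so the null distribution remains exchangeable with the real score.

## Known limitations

* Bayes factors use point-estimated hyperparameters; nesting
  monotonicity of the *optimized* marginals is not guaranteed (local
  optima), so the test suite asserts calibration, not monotonicity.
* The ARD lengthscale of a binary covariate is only weakly identified
  when the covariate is irrelevant; the permutation null absorbs this.
* The hierarchical ρ ≤ 1 tie is a modeling choice, not a theorem; with
  many batches the unconstrained model becomes identifiable and the tie
  could be relaxed.
* Sparse/inducing-point approximations and non-Gaussian likelihoods are
  out of scope; fits are exact O(n³) and intended for n up to a few
  thousand observations.
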