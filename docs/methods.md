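# Methods

This note records the models, the assumptions behind them, and the design
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Endpoints and quality control

The growth endpoint is the specific growth rate
`SGR = (ln X_j − ln X_i)/(t_j − t_i)` in d⁻¹ over the 72 h exposure; the
photophysiology endpoint is the light-adapted effective quantum yield
`ΔF/Fm′ = (Fm′ − F)/Fm′` at 24 h. Percent inhibition of a replicate is
taken against the **mean** of the control group,
`100·(X̄_c − X)/X̄_c`; the treatment-level inhibition is the mean of its
replicate values, so treatment-level numbers match the group-mean formula
while replicate-level values remain available for the bootstrap and the
NEC likelihood. Negative inhibition (stimulation) is kept, not truncated:
truncation would distort the error structure the fits rely on.

Solvent controls are pooled with seawater controls only after a
non-significant one-way ANOVA between the two groups (α = 0.05); a
significant difference raises a `solvent_effect` flag and keeps them
separate. Validity rules: mean control SGR ≥ 0.92 d⁻¹ (boundary valid),
and pre-exposure yields must exceed 0.45 strictly. The wells schema
carries no separate pre-exposure plate read, so the pipeline applies the
yield screen to the unexposed (control) wells as the closest observable
surrogate.

## Exposure chemistry

The analysis concentration is built in two steps. (1) Each measured
treatment gets a time-weighted average, the geometric mean
`√(c_0h · c_72h)` — the correct time average under first-order decay.
(2) The mean TWA/nominal ratio over the measured treatments of one
herbicide (its *loss factor*) multiplies every nominal concentration,
including treatments without chemistry. Factors outside (0.5, 1.2] are
logged as suspicious and outside (0, 1.5] rejected. A 72 h non-detect is
substituted by half the limit of detection (configurable); the loss factor
is computed per herbicide per assay. All downstream fits use the adjusted
(analysis) concentrations.

## Four-parameter logistic ECx

Mean inhibition is `y(c) = b + (t − b)/(1 + 10^{(L − log10 c)·h})` with
bottom `b`, top `t`, `L = log10 EC50` and hill slope `h > 0` (monotone
non-decreasing). The fit is nonlinear least squares (trust-region
reflective, analytic Jacobian) on per-replicate inhibition against log10
analysis concentration. Controls cannot sit at log(0); they enter through
the inhibition normalisation, and the bottom is estimated but initialised
at 0 and bounded to [−20, 20] (tolerating stimulation) while the top is
bounded to [50, 110] — the curves this assay produces span 0 → ~100 %.
Non-convergence is flagged, never silently replaced.

ECx is defined **absolutely**: the smallest c with y(c) = x, solved in
closed form from the fitted parameters, so EC50 equals the EC50 parameter
only when b + t = 100. When the fitted curve never reaches x % below the
maximum tested concentration the estimate is censored and rendered
"> max tested" (e.g. ">3,700").

Confidence intervals use a nonparametric within-treatment case bootstrap
(the reference implementations of this assay type report CIs from
closed-source software whose method is unstated, so the interval method is
this package's own choice): each resample draws **m = n−1** replicates
with replacement within the control group and within each treatment,
recomputes inhibition against the resampled control mean, refits, and
re-interpolates; the 95 % interval is percentile. The m = n−1 size
(Davison & Hinkley) is used because the empirical distribution of n values
has variance (n−1)/n·s², so n-out-of-n resampling understates group-mean
variance by 20 % at n = 5; with m = n−1 the resampled group mean has
variance exactly s²/n. A residual narrowing remains because the plug-in
spread E[s] = c₄σ ≈ 0.94σ at n = 5; simulation (see the acceptance
script) puts realised coverage near the low end of the nominal band. With
n = 5 replicates this is inherent to any plain case bootstrap.

Derived summaries: `ReP = EC50(ref)/EC50(test)` (> 1 ⇒ more potent than
the diuron reference); the per-herbicide EC50 ratio SGR : ΔF/Fm′ with its
arithmetic mean; and an OLS regression (with intercept) of the growth
EC50s on the quantum-yield EC50s. The intercept is retained because the
through-origin fit does not reproduce the published slope/R² pair while
the intercept fit does. One-way ANOVA is the classical F test; no
multiple-testing correction is applied (none is used in this assay
tradition).

## Bayesian threshold-exponential NEC

The proportional response `Y = 1 − inhibition/100` of the growth endpoint
follows a segmented (Fox-type) model on log concentration x:

    E[Y|x] = α exp(−β (x − γ) 𝟙[x > γ]) − Δ,    Y ~ N(E[Y|x], σ²)

flat at α − Δ up to the threshold γ (the NEC on the log axis), then an
exponential decay at rate β. The indicator is strict (𝟙[x > γ]); the mean
is continuous at γ so the choice is numerically immaterial. Priors exactly
as stated for this model family, with normals parameterised by
**precision**: α ~ N(0, 0.1), β ~ Gamma(10⁻⁴, 10⁻⁴), γ ~ N(0, 0.01),
Δ ~ N(0, 0.1), σ ~ Uniform(0, 29]. The α prior (SD ≈ 3.16) is very
diffuse for a response near 1; it is implemented as stated, not
"improved". The yield endpoint is not fed to this model — thresholds for
it are reported from the 4PL side only.

Concentrations enter as natural log of the analysis concentration
(configurable to log10; the back-transform follows the same base).
Controls (concentration 0) are anchored at the pseudo-log-concentration
log(lowest treatment/10); they pin down α, and the NEC is insensitive to
the divisor as long as the pseudo-point sits clearly below the lowest
treatment.

Sampling is random-walk Metropolis with adaptation **during burn-in
only**: a first component-wise stage calibrates marginal step sizes and
moves the chain into the mode region, then a joint stage uses multivariate
normal proposals whose covariance tracks the post-transient chain history
(scaled 2.38²/d, Haario-style) with a global step multiplier tuned toward
an acceptance rate of ~0.3 (band 0.2–0.4). The kernel is frozen for the
sampling phase, preserving detailed balance. Per-chain RNG streams are
spawned deterministically from the master seed. Defaults: 5 chains,
20,000 burn-in, 10,000 kept draws. Convergence is diagnosed by split R̂
(≤ 1.05) and ESS (≥ 400 per parameter); failures flag the result and are
never silent. Prior-only sampling (likelihood disabled) uses the
component-wise kernel — the prior factorises, and the β prior's spike at
0 with a 10⁴ variance makes joint covariance estimation pathological;
direct prior draws (`sample_prior`) are also provided and are the right
tool for checking the heavy-tailed β prior.

The NEC point estimate is the posterior **median** of exp(γ) (the point
functional is not pinned down in this model tradition; the mean is also
emitted), with an equal-tailed 95 % credible interval obtained by
back-transforming the γ quantiles. A posterior ECx (concentration where
the mean response has declined x % from α − Δ) is available but off by
default; threshold tables take ECx from the 4PL fits.

Known limitation: on strongly sigmoidal data the (α, Δ) pair is weakly
identified (only α − Δ is well constrained near the plateau) and chains
can disagree; the R̂/ESS flags catch this, and longer chains or fixing
Δ = 0 are the remedies.

## Synthetic bioassay generator

The generator emulates the study design: 5 replicates per treatment,
seawater control (optional solvent control generated identically — the
assay tradition finds no solvent effect at ≤ 0.01 % v/v), a diuron
reference (default 4 µg L⁻¹; 2 µg L⁻¹ is a config option for the
simazine-type assay), exponential growth from 3 × 10³ cells mL⁻¹ over
3 d, fluorescence plates at 3.5 × 10⁵ cells mL⁻¹, control SGR 1.2 d⁻¹ and
control yield 0.5 by default. Ground truth is either a 4PL inhibition
curve or a threshold-exponential response.

Noise is gaussian **on the endpoint scale** (SGR in d⁻¹, yield as a
fraction), not on raw counts, because replicate variability in this assay
type is reported on the endpoint scale; defaults `noise_sd_sgr = 0.04`
and `noise_sd_yield = 0.01` sit mid-range of the reported control SDs
(0.01–0.07 and ~0.01). Yields are clipped to the physical PAM range
[0, 0.75] (clipping logged). Reference wells are generated from fixed
reference inhibition levels (31.4 % SGR, 80.2 % yield — study-wide means
for the diuron reference) rather than from the test herbicide's truth,
since the reference is a different compound. Chemistry: 0 h measurements
scatter around nominal with CV 2 %, and the 72 h value is
`(1 − loss_fraction)` of it; the default loss of 0.3 gives a TWA ≈ 84 %
of nominal — inside the "within 20 % of nominal" class, with 0–50 %
losses representable. Each generator (growth, yield, chemistry) draws
from its own stream spawned from the master seed, so outputs are
individually bit-reproducible.

What the generator does **not** emulate: flow-cytometer counting error
and gating, plate-position effects, physicochemical drift, between-assay
batch effects (each simulated assay has one fixed control mean), and
non-gaussian tails. Passing tests therefore demonstrate correctness of
the estimation machinery under the design's nominal error model, not
robustness to instrument artefacts.

## Problem sizes and numerical choices

Simulation studies in the test suite and acceptance script are sized to
give tight Monte-Carlo error at reasonable runtime, as this package's own
choices: NEC parameter recovery uses 100 datasets with 3 chains ×
(2,000 burn-in + 1,500 kept) — mixing at these lengths gives R̂ ≈ 1.03
and is sufficient for interval coverage; bootstrap calibration uses 200
simulated assays × 1,000 resamples; prior checks use 10⁶ direct draws and
4 × (2,000 + 4,000) prior-only MCMC iterations. Full-length MCMC
(5 × 30,000) remains the library default. 4PL fits use tolerances 1e-15
(1e-10 inside the bootstrap), bounded parameters as above, and a
mid-response initial guess; the ECx inversion is closed-form. Degenerate
inputs (non-positive densities or concentrations, F > Fm′, empty groups,
zero within-group variance in ANOVA) raise structured errors rather than
propagating NaNs.
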