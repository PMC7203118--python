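# phycotox

Analysis pipeline for marine-microalgal herbicide toxicity bioassays: from
replicate-level cell densities and PAM fluorescence to concentration–response
thresholds (EC10/EC50), Bayesian no-effect concentrations (NEC), relative
potencies and an endpoint-sensitivity comparison.

## The problem

Growth-inhibition bioassays expose a microalga (here a marine cryptophyte,
*Rhodomonas salina*) to an ascending ladder of herbicide concentrations with
five replicate vessels per treatment, a seawater (and optionally solvent)
control and a diuron reference treatment. Two endpoints are measured:

* **Specific growth rate** over 72 h,
  `SGR = (ln X_j − ln X_i) / (t_j − t_i)` (d⁻¹), from cell densities
  `X_i, X_j`; the assay is valid only if mean control SGR ≥ 0.92 d⁻¹.
* **Effective quantum yield** of PSII after 24 h,
  `ΔF/Fm′ = (Fm′ − F)/Fm′`, from light-adapted PAM fluorometry, with a
  pre-exposure screen requiring ΔF/Fm′ > 0.45.

Percent inhibition of each treatment replicate is
`100·(X̄_control − X)/X̄_control`. All fits run on *measured* exposure:
the geometric mean of the 0 h and 72 h chemistry (a time-weighted average)
defines a per-herbicide loss factor that is applied to every nominal
concentration.

## The models

**Four-parameter logistic (ECx).** Mean inhibition follows
`y(c) = bottom + (top − bottom)/(1 + 10^((log10 EC50 − log10 c)·hill))`,
fit by least squares to per-replicate inhibition. ECx is the concentration
giving an *absolute* x % inhibition relative to control, interpolated from
the fitted curve and censored as "> max tested" when unattained. 95 % CIs
come from a within-treatment case bootstrap (m = n−1 resampling,
percentile intervals). Relative potency is
`ReP = EC50(diuron)/EC50(herbicide)`.

**Threshold-exponential NEC (Bayesian).** The proportional response
`Y = 1 − inhibition/100` declines with log concentration `x` as

```
E[Y|x] = α · exp(−β (x − γ) 𝟙[x > γ]) − Δ,   Y ~ Normal(E[Y|x], σ²)
```

so the expected response is exactly flat below the no-effect concentration
`exp(γ)`. Priors (normals as mean/precision): α ~ N(0, 0.1),
β ~ Gamma(10⁻⁴, 10⁻⁴), γ ~ N(0, 0.01), Δ ~ N(0, 0.1), σ ~ U(0, 29).
Sampling is adaptive random-walk Metropolis (five chains, 10,000 kept
draws after a 20,000-iteration burn-in by default) with split-R̂/ESS
convergence flags.

Because no raw data are deposited with published studies of this design,
the package ships a synthetic bioassay generator (`phycotox.simulate`) that
reproduces the study design — 5 replicates, exponential growth from
3 × 10³ cells mL⁻¹, control yields ≈ 0.45–0.53, endpoint-scale gaussian
noise, chemistry losses — with a ground-truth sidecar so every stage can be
scored exactly.

## Worked example

```python
import numpy as np
from phycotox import (AssayDesign, NECExpTruth, GroundTruth, FourPLModel,
                      build_endpoint_table, build_exposure_series,
                      bootstrap_ecx, NECModel)
from phycotox.simulate import simulate_growth_wells, simulate_chemistry

design = AssayDesign("diuron", (0.3, 1, 2, 4, 8, 16, 32))
truth = GroundTruth(model=NECExpTruth(gamma=np.log(1.7), beta=0.8), seed=7)
wells = simulate_growth_wells(design, truth)
endpoints = build_endpoint_table(wells, "sgr")
exposure = build_exposure_series(simulate_chemistry(design, truth))

nec = NECModel.from_endpoints(endpoints, exposure).fit(
    chains=5, burn_in=4000, draws=2000, seed=0)
print(nec.summary())
```

prints

```
Bayesian NEC threshold-exponential model
----------------------------------------------------------
chains x kept draws: 5 x 2000 (burn-in 4000)
converged: True (max R-hat 1.010, min ESS 475)

param        mean        sd      2.5%     97.5%   R-hat     ESS
alpha       1.002   0.03204    0.9431     1.068   1.005     572
beta       0.8073   0.07172    0.6734    0.9473   1.007     584
gamma      0.2853   0.03328    0.2185    0.3452   1.010     475
delta    -0.02099   0.03059  -0.07587   0.04138   1.006     614
sigma     0.03228  0.003884   0.02587   0.04117   1.004     500

NEC (concentration scale): 1.332 (1.244-1.412) 95% CrI
```

The generating no-effect concentration was 1.7 µg L⁻¹ nominal; after the
simulated 30 % chemistry loss the truth on the analysis axis is
1.43 µg L⁻¹, and the posterior lands at 1.33 (1.24–1.41) for this seed.
`alpha ≈ 1` and `delta ≈ 0` say controls sit at an unperturbed
proportional response of one. The same endpoint/exposure tables feed the
4PL side:

```python
est = bootstrap_ecx(endpoints, exposure, 50, n_boot=1000, seed=0)
print(est.point, est.ci_low, est.ci_high)
```

A command-line interface mirrors the library
(`phycotox simulate | endpoints | chem | fit-ecx | fit-nec | compare |
report | all`); `phycotox compare` reproduces the endpoint-sensitivity
summaries from a table of EC50 pairs, e.g. with the bundled reference
thresholds it prints `mean EC50 ratio: 4.28; slope 3.489, R^2 0.871` —
growth EC50s sit on average ≈ 4× above the quantum-yield EC50s, i.e. the
photosynthesis endpoint is the more sensitive one.

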