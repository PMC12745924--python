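# Methods

This note documents the models, the synthetic study conditions, the numerical
choices, and the places where the design was genuinely open.

## Life cycle and time step

The modelled animal is a small viviparous skink: neonates of ~35 mm SVL are
born in a September–January window (one litter per female per year, at most
eight offspring), grow along a von Bertalanffy curve toward a sex-specific
asymptote (females 79 mm, males 71 mm), mature at 54 mm (females), and face a
Gompertz (exponentially age-increasing) mortality hazard modulated by the
monthly environment. The time step is one calendar month everywhere —
matching monthly trap checks — and ages are in months. Projection models are
female-based with a 0.5 birth sex ratio.

## Growth

Fabens' parameterisation uses recapture triples (L₀, L₁, Δt), so no ages are
required. Individual heterogeneity enters as `kᵢ ~ Normal(k, k_sd)`; the
marginal likelihood integrates the scalar random effect by 20-node
Gauss–Hermite quadrature and is maximised by a staged Nelder–Mead search
(fixed-effects fit first, then a short profile over candidate random-effect
SDs, then a simplex restart from the incumbent — the (k_sd, σ) ridge can
stall a single simplex run). Convergence tolerance is 6e-6 with a 5000
iteration budget. Initial values: L∞ from the largest observed SVL, *k* from
a moment estimate of mean growth increments.

Conditional R² is computed as the squared Pearson correlation between
conditional (empirical-Bayes, individual-level) predictions and observed
recapture lengths; no standard formula exists for this quantity in nonlinear
mixed models, so the choice is documented here and kept pluggable.

Two growth spreads play different roles:

* `sigma_` (the Fabens residual SD) mixes measurement error (~1 mm ruler)
  with real growth variation and is reported with the fit;
* projection kernels use the **process** spread implied by individual *k*
  heterogeneity, `k_sd · (L∞ − 55 mm)` (the one-month increment spread of a
  mid-sized animal, floored at 0.15 mm so the density is resolvable on a
  ~1 mm mesh). Using the raw residual SD in the kernel systematically
  depresses λ, because inflated spread pushes adults across the senescent
  tail of the survival function; the recovery experiments in
  `tests/test_acceptance.py` quantify this.

The age axis is anchored so the predictive curve passes through the neonate
size at age 0 (t₀ is derived, not fitted; it is never observable in
mark-recapture data).

## Age-dependent survival

Hazard `h(a) = exp(b₀ + b₁ a)` per month, survivorship
`S(a) = exp((e^{b₀}/b₁)(1 − e^{b₁ a}))` (exponential at b₁ = 0). The
likelihood is a capture-recapture likelihood conditioned on first capture:
monthly survival `S(a+1)/S(a)` at the individual's (growth-curve-assigned)
age, constant detection probability, and the unknown death month summed out
by the chi recursion. Ages at first capture are treated as known plug-ins —
the standard practice; error in them attenuates b₁ slightly, which is the
main residual bias in the end-to-end run. Priors: Normal(0, 10²) on b₀,
half-Normal(0, 1) on b₁ (hazard may not decline with age). Sex enters as
separate (b₀, b₁) pairs.

Sampling uses an affine-invariant ensemble (emcee), walkers initialised in a
tight ball around the posterior mode (found by Nelder–Mead) so short chains
start in stationarity; acceptance requires split-chain potential scale
reduction < 1.05 for every parameter, otherwise the fit raises. Defaults
(24 walkers × 2500 steps, 1000 burn-in, thin 5) are desk-scale; all settings
are constructor arguments.

## Environment-dependent survival (CJS)

Monthly covariates (maximum temperature, precipitation, mean SVL of that
month's captures) are z-scored for optimiser stability; the scaling is stored
in the fit so predictions accept raw-scale covariates, and the
reparameterisation leaves the maximised likelihood unchanged (tested).
Because covariates vary in time but not among individuals, the per-occasion
φ and p series are shared, and one likelihood evaluation is
O(occasions + detections) via cumulative sums plus the chi recursion — this
is what makes fitting 64 models × many seeds cheap. The model set is the
full additive cross of covariate subsets on φ and p (intercepts always
present), ranked by AIC with ties broken toward fewer parameters.
Non-converged models are flagged in the table, never dropped. Months without
captures carry the overall mean SVL and an explicit flag.

A caution from the null simulations: with constant true φ and p, best-of-64
selection noise gives the intercept-only model a median AIC gap near 1.5 to
the winner but a heavy upper tail (occasionally 6–9), so "the null is within
2 AIC" holds only in about half of replicates; the tests assert the measured
behaviour.

## Fecundity

Litter size is zero-truncated (a gravid female has at least one embryo) and
capped at eight. The default family is truncated Poisson with a log link on
centred SVL; a truncated negative binomial is available. Fits are sampled
with mode-initialised emcee; pointwise log-likelihoods are retained and
models are compared by PSIS-LOO. The quantity exported to the IPM is the
posterior-predictive mean litter with the cap applied (`mean_litter_`). The
projection models use a *constant* litter for all mature females — the
size-dependence question is surfaced by the fitted slope and its credible
interval but deliberately not propagated into F.

## IPM assembly and eigen-analysis

Midpoint rule, 50 mesh cells on [30, 85] mm (~1.1 mm resolution; λ changes
by < 1% against a 500-point mesh). The growth transition G is a discretised
Gaussian per column, renormalised to sum to one — eviction is handled by
renormalisation so that the P column sums equal S(x) exactly, keeping P
substochastic through survival only. F divides the annual litter evenly
across the five breeding months (a single-pulse alternative is a parameter),
gates recruitment at 54 mm, and places offspring by a discretised neonate
Gaussian (error if > 1% of its mass falls outside the mesh). Survival
combines the two fitted sources on the logit scale,

    logit S(x, e) = logit S_size(x) + [logit φ(e) − logit φ(ē)],

so S reduces exactly to the size-dependent survival at the mean environment;
the synthetic generator uses the same convention, making the combination
rule self-consistent between simulation and fitting. Sizes at or above L∞
are clamped just below the asymptote (with a warning): their assigned age,
and hence hazard, is effectively maximal.

Dominant eigenvalues come from power iteration (tolerance 1e-10) on a
diagonally shifted matrix — the shift makes iteration converge even for
periodic nonzero patterns and is subtracted back exactly; primitivity is
checked by boolean reachability and reducible matrices raise. R₀ is the
dominant eigenvalue of `F̄ (I − P̄)⁻¹` on the mean monthly kernel and the
generation time is `T = ln R₀ / ln λ` in months (undefined, and flagged NaN,
at λ = 1). The monthly λ series is the per-month kernel eigenvalue (not a
rolling 12-month root; the yearly product eigenvalue is reported separately
and is *not* the 12th power of the monthly geometric mean — the two metrics
answer different questions). Elasticities use the standard `v w/⟨v,w⟩`
surface; vital-rate elasticities perturb S, F (multiplicatively, ±0.1%) and
*k* (rebuilding G, since rescaling a column-normalised transition is a
no-op), recomputing λ each time.

## Time-series decomposition

Classical additive decomposition (centred 12-month moving average trend,
month-wise mean seasonal re-centred to zero, residual remainder), via
statsmodels. Variance shares are normalised component variances over months
where all components are defined — chosen because the three shares then sum
to one, matching how such shares are conventionally reported; a range-based
definition would not. Additive (not multiplicative) because survival and λ
series do not cross zero and their seasonal amplitude does not scale with
the level.

## Spatial projection

Pixels are independent demographic units (no dispersal). The analysis region
is the minimum convex polygon of occurrence points; climate stacks are
cropped to its bounding box plus a 2° buffer. Covariates are screened by
iteratively dropping the highest VIF until all ≤ 5 (infinite VIF from exact
collinearity drops the larger column index first). Per pixel and year, 12
monthly kernels are built from the pixel's climate (mean SVL held at its
study mean — future size structure is unobservable) and multiplied; period
means and SDs of yearly λ are aggregated over the years within each window
(SD over years, not months). Rasters are float32 multi-page GeoTIFFs
(minimal tag set: pixel scale, tie point, WGS84 geokeys) written and read
with tifffile; row 0 is the northernmost row and pixel centres are used for
point-in-polygon masks. Scenario labels (e.g. SSP2-4.5 / SSP5-8.5) are
opaque tags on the input stacks; no climate-model logic lives here.

## Synthetic study conditions

The generator's defaults are fixed once and define the study conditions:

| parameter | default | basis |
|---|---|---|
| L∞ (F/M) | 79 / 71 mm | sex-specific asymptotes of the study species |
| k | 0.094 /month | places maturity (54 mm) near 6 months of age |
| k_sd | 0.012 | moderate individual growth heterogeneity |
| neonate SVL | 35 ± 1.5 mm | recruitment-season neonates |
| b₀, b₁ | −3.5, 0.02 | a few % of a cohort reaches 5 years; senescent |
| β_tmax on logit φ | −0.5 per SD | adverse effect of maximum temperature |
| detection | logit⁻¹(−1.7) ≈ 0.15/month | sparse monthly pitfall capture |
| breeding window | Sep–Jan | parturition synchronised with early rains |
| litter | Poisson, truncated ≥ 1, capped 8 | single annual litter |
| SVL measurement error | 0.5 mm | 1 mm-precision ruler |
| climate | seasonal sinusoid + trend + noise; wet season Oct–May | tropical savanna |

For stationary experiments the litter rate is *calibrated* (Brent root
finding on the truth kernels) so the true geometric-mean monthly λ equals 1;
under these mortality defaults that solution is ≈ 3.3, comfortably inside
the 1–8 biological range. Environmental effects act additively on the logit
of monthly survival after the Gompertz age term — the generator and the
kernel combiner share this single convention.

What the generator does **not** emulate: spatially autocorrelated climate
noise, movement between pixels, demographic closure (recruits are seeded
exogenously rather than born from simulated mothers, which is irrelevant for
parameter recovery but means simulated abundance trajectories are not
themselves projections), fire-regime covariates, and trap-level detection
heterogeneity. Passing recovery tests therefore demonstrates estimator
correctness under the stated generative model, not robustness to these
real-data complications.

## Problem sizes used in tests and the acceptance script

Recovery suites run at the study's own scales: ~170 recaptured individuals
for growth, 500 individuals for Gompertz recovery, 800 for CJS sign
recovery over 25 seeds, 30 gravid females in the pipeline, a 10 × 10 × 10-yr
toy grid for the spatial checks, and a 1000-individual, 182-month run in the
acceptance script. MCMC defaults are desk-scale equivalents of the
field-scale settings (which were 50,000 steps / 5001 burn-in / thin 50 / 4
chains for mortality, and 4 × 4000 iterations / 2000 warmup for fecundity)
and are exposed as parameters.

## Known limitations

* Plug-in ages from the growth curve attenuate the Gompertz slope
  (errors-in-variables); posterior uncertainty in ages is not propagated.
* The CJS model is single-state, conditioned on first capture; no
  goodness-of-fit (median-ĉ) machinery.
* Generation time `ln R₀ / ln λ` is numerically delicate near λ = 1 when R₀
  and λ come from different kernels; here both derive from the same mean
  kernel, which keeps the ratio stable.
* Density dependence, stochastic-environment λ_s and two-sex dynamics are
  out of scope.
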