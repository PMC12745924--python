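# skinkipm

Environment-dependent demography for a small viviparous Neotropical skink,
from monthly mark-recapture data to spatially explicit population projections.

The package is aimed at population ecologists working with open-population
capture-recapture data on size-structured ectotherms. It estimates the four
vital-rate components of a monthly, size-structured life cycle and composes
them into Integral Projection Models (IPMs):

1. **Growth** — von Bertalanffy in the Fabens parameterisation (no ages
   needed), `L₁ = L₀ + (L∞ − L₀)(1 − e^(−kΔt))`, fitted as a nonlinear mixed
   model with individual variation in the growth coefficient *k*; inverting
   the curve, `a = t₀ + (1/k)·ln(L∞/(L∞ − L))`, assigns ages from body size
   (SVL, snout-vent length in mm).
2. **Age-dependent survival** — Gompertz mortality, hazard
   `h(a) = exp(b₀ + b₁a)`, estimated by MCMC from capture histories with
   ages assigned via the growth curve, detection ≤ 1 and right-censoring
   handled by marginalising the latent death month.
3. **Environment-dependent survival** — Cormack–Jolly–Seber (CJS) models
   with monthly covariates (maximum temperature, precipitation, mean SVL of
   captures) on both survival φ and detection p; all 2³ × 2³ = 64 additive
   models are fitted and ranked by AIC.
4. **Fecundity** — Bayesian zero-truncated count regression of litter size
   on female SVL, compared by PSIS-LOO, with the biological cap of eight
   offspring.

Monthly kernels `K(y,x) = G(y|x)·S(x) + F(y,x)` are discretised by the
midpoint rule on 50 mesh points over 30–85 mm. Survival combines the size
baseline and the CJS environmental deviation on the logit scale; reproduction
is restricted to the September–January breeding season and recruits enter at
a Gaussian neonate size (~35 mm). The yearly matrix is the chronological
product of 12 monthly kernels; its dominant eigenvalue is the yearly growth
rate λ, with stable structure *w*, reproductive values *v*, net reproductive
rate R₀, generation time `T = ln R₀ / ln λ`, and sensitivity/elasticity
surfaces. Per-pixel kernels projected over climate raster stacks give
λ maps by period and emission scenario.

A first-class synthetic-data generator (`skinkipm.synthetic`) simulates the
whole observation process with known truth — seasonal climate, von
Bertalanffy growth with individual heterogeneity, Gompertz mortality
modulated by temperature, seasonal breeding, imperfect monthly detection —
so every estimator is testable by parameter recovery, and the package is
fully runnable without any external data.

## Worked example

```python
from skinkipm.pipeline import run_pipeline

manifest = run_pipeline({
    "seed": 7,
    "output_dir": "demo_out",
    "synthetic": {"n_individuals": 800, "n_months": 120},
})
print(manifest["results"])
```

This simulates a stationary-calibrated population (truth litter size solved
so the true geometric-mean monthly λ is exactly 1), refits every stage from
the simulated captures alone, and prints:

```
{'lambda_geometric_mean': 0.9993884260854817}
```

i.e., the pipeline recovers the stationary growth rate to within about 0.1%.
`demo_out/` then contains the AIC table of all 64 CJS models, the fitted
growth/mortality/fecundity parameters (JSON), monthly survival and λ series
(CSV), their seasonal decompositions, and a manifest with seeds and file
hashes. The same stages are exposed as a CLI:

```bash
skinkipm simulate --n-individuals 400 --n-months 60 --out sim/
skinkipm run --seed 7 --out demo_out
skinkipm decompose --series demo_out/monthly_lambda.csv
skinkipm project --tmax-stack tmax.tif --precip-stack precip.tif \
    --fits fits.json --scenario ssp245 --out maps/
```

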