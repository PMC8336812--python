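# distreg — Bayesian distributional regression for child growth

Chronic childhood malnutrition (stunting) is conventionally studied by
regressing the height-for-age z-score (HAZ) on socio-economic and
environmental covariates — a model for the **mean** only. But covariates
also shape the **spread** of HAZ: the same village can host both
well-nourished and severely stunted children, and that dispersion
carries its own policy signal. This package implements a Bayesian
Gaussian *location–scale* (distributional) regression in which **both**
parameters of

```
HAZ_i ~ N(mu_i, sigma_i^2)
```

carry structured additive predictors:

```
mu_i        = x_i' beta  + f_1(assets) + f_2(age, bf months) + f_3(age, mother age)
              + f_4(education) + ... + f_10(pop. density) + f_spat(district, wave)
log sigma_i = x_i' alpha + analogous smooth and spatial terms
```

with

- **P-splines** (cubic B-splines, random-walk difference penalties) for
  nonlinear covariate effects,
- **tensor-product surfaces** for two-way interactions
  (child age x breastfeeding duration, child age x maternal age),
- an **intrinsic Markov random field** (MRF) over the district adjacency
  graph, estimated separately per survey wave, for smooth spatial effects,
- **effect-coded** categorical covariates (gender, urban/rural, wave),
- sum-to-zero constraints on every smooth for identifiability.

Estimation is by MCMC: exact conjugate Gibbs draws for all mean-side
blocks and their smoothing variances, and iteratively-weighted
least-squares Metropolis–Hastings (IWLS-MH) for scale-side blocks.
A six-model grid (means-only through full location-scale) is compared by
DIC and WAIC; diagnostics include quantile residuals, effective sample
sizes and simultaneous credible bands.

Because household survey microdata cannot be redistributed, the package
ships a calibrated synthetic generator that emulates a two-wave
DHS-style child survey (sample sizes, covariate moments, wealth-index
construction from binary assets, cluster-level GPS displacement, and a
district lattice with rook adjacency).

## Worked example

```bash
distreg simulate --seed 20 --n-2007 800 --n-2013 1200 --side 4 --out results/survey
distreg report --survey results/survey/survey.csv \
    --edges results/survey/district_edges.txt \
    --nodes results/survey/district_nodes.txt \
    --seed 21 --iterations 1500 --burn-in 500 --thinning 4 \
    --n-intervals 10 --tensor-intervals 5 --out results/model_grid
```

On this 2 000-child simulation the model comparison table
(`results/model_grid/model_comparison.tsv`) reads:

```
 model    DIC   pD   WAIC  pWAIC
     1 6893.8 40.5 6893.9   79.3   means-only, full predictor
     2 6763.9 68.4 6767.8  135.6   socio-economic covariates, both parameters
     3 6969.4 39.3 6970.5   77.8   remote-sensed covariates, both parameters
     4 6968.2  7.5 6968.4   15.4   linear terms only
     5 6777.6 78.3 6782.3  154.4   full location-scale
     6 6775.0 71.7 6778.2  140.5   full location-scale without pop. density
```

Every heteroscedastic specification beats its means-only counterpart;
at this reduced sample size the parsimonious socio-economic model (2) is
selected by both criteria, with the full models (5, 6) close behind.
The fitted linear effects of the selected model:

```
predictor      covariate  posterior_mean  ci_lower  ci_upper
       mu      intercept          -1.578    -1.637    -1.520
       mu gender[female]           0.053    -0.002     0.107
       mu   urban[rural]          -0.033    -0.093     0.025
    sigma      intercept           0.253     0.221     0.283
    sigma gender[female]          -0.042    -0.069    -0.013
```

i.e. a mean HAZ of −1.58, a residual scale of exp(0.253) ≈ 1.29, girls
slightly taller-for-age and slightly less dispersed than boys. Smooth
term curves (`curve_*.tsv`), per-district spatial effects
(`spatial_effect.tsv`) and quantile residuals (`residuals.tsv`) are
written alongside. The numbered scripts in `analysis/` reproduce this
run end to end; `analysis/04_summarise.py` rebuilds the summary above
(`results/summary.txt`).

## Layout

- `src/distreg/` — all computation: `bases` (splines, penalties, MRF),
  `model` (model grid, design assembly), `mcmc` (samplers),
  `evaluate` (DIC/WAIC, residuals, bands, effect extraction),
  `synthetic` (survey generator), `pipeline` + `cli` (orchestration).
- `analysis/` — thin numbered drivers writing to `results/`.
- `docs/methods.md` — model, priors, algorithms and design choices.
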