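# Methods

## Model

For child $i$ the height-for-age z-score is modelled as
$y_i \sim N(\mu_i, \sigma_i^2)$ with structured additive predictors on
both parameters:

$$\mu_i = \eta_i^\mu, \qquad \sigma_i = \exp(\eta_i^\sigma),$$

$$\eta_i = x_i'\beta + \sum_j f_j(z_{ij}) + f_{\text{tens}}(z_{i1}, z_{i2})
 + f_{\text{spat}}(s_i, w_i).$$

The exponential link keeps $\sigma_i$ positive without constraining the
predictor. The scale predictor may carry any subset of the mean-side
terms except the two tensor surfaces (interactions of that order in the
scale are practically unidentifiable at survey sample sizes).

### Term types and priors

- **P-splines.** Cubic B-splines on equidistant knots (default 20
  interior intervals, reduced automatically for discrete covariates with
  few distinct values), with a Gaussian random-walk prior on the
  coefficients, i.e. an improper normal with precision $K/\tau^2$,
  $K = D_r'D_r$ the $r$-th order difference penalty (default $r = 2$).
- **Tensor products.** Row-wise Kronecker (Khatri–Rao) product of two
  marginal B-spline bases with the Kronecker-sum penalty
  $K_1 \otimes I + I \otimes K_2$ and a single variance parameter.
- **Spatial effect.** Intrinsic MRF / ICAR over the district adjacency
  graph: $K = \operatorname{diag}(N_s) - A$, so each district effect is
  conditionally normal around the mean of its neighbours with variance
  $\tau^2 / N_s$. The effect is estimated separately per survey wave
  (block-diagonal penalty $I_{\text{waves}} \otimes K$). Islands
  (zero-degree districts) are permitted and produce a warning.
- **Fixed effects.** Intercept plus effect-coded (+1/−1) categorical
  covariates under a diffuse prior.
- **Identifiability.** Every smooth is constrained to sum to zero over
  the sample (per wave for the MRF) by reparameterising with an
  orthonormal basis of the constraint null space; the penalty and its
  rank deficiency are transformed accordingly.
- **Variance parameters.** Conjugate inverse-gamma
  IG(0.001, 0.001) on every smoothing variance, updated as
  IG$(a + \operatorname{rk}(K)/2,\; b + \beta'K\beta/2)$.

### Model grid

Six specifications are compared: (1) full mean predictor with constant
scale; (2) socio-economic terms only, both parameters; (3)
remote-sensed/environmental terms only, both parameters; (4) linear
terms only; (5) the full location-scale model; (6) model 5 without the
population-density smooth. Comparison uses DIC (plug-in at the
posterior means of the *fitted* $\mu_i, \sigma_i$, which is well defined
under the exponential link) and WAIC with the variance-based penalty
$p_{\text{WAIC2}}$.

## Estimation

A systematic-scan MCMC sweep per iteration (defaults: 12 000
iterations, 2 000 burn-in, thinning 10):

- **Mean side (exact Gibbs).** Given $\sigma$, each block has the
  Gaussian full conditional $N(P^{-1}b, P^{-1})$ with
  $P = B'\Sigma^{-1}B + K/\tau^2$, $b = B'\Sigma^{-1}r$ over partial
  residuals $r$, drawn via Cholesky of the precision.
- **Scale side (IWLS-MH).** For the Gaussian log-scale the expected
  information per observation is the constant 2, so the IWLS Gaussian
  approximation has *state-independent* precision $2B'B + K/\tau^2$ and
  only its mean moves with the working response
  $z = \eta + (e^2 e^{-2\eta} - 1)/2$. One Cholesky per update serves
  both proposal and acceptance correction. Observed acceptance rates
  are typically above 0.9. An adaptive random-walk proposal
  (Robbins–Monro scale tuning during burn-in only) is available as a
  fallback.
- **Burn-in assist.** Far from the mode the state-independent proposal
  makes acceptance of an otherwise good jump vanishingly small (the
  reverse-proposal density collapses), which can pin a short chain at
  its starting value. During burn-in only, a rejected IWLS proposal
  therefore moves the state halfway towards the IWLS conditional mode —
  a damped Newton step. Burn-in draws are discarded, so the
  post-burn-in transition kernel is untouched; its stationary law is
  verified directly against brute-force grid densities in the test
  suite (total variation < 0.02).

Pointwise log-likelihoods, coefficient and variance traces, and running
means of the fitted $\mu_i, \sigma_i$ are stored at every saved
iteration. Chains persist as delimited text plus a JSON manifest.

## Diagnostics

- **Quantile residuals** $(y_i - \hat\mu_i)/\hat\sigma_i$, clipped at
  ±8, tested against N(0, 1) by Kolmogorov–Smirnov.
- **Effective sample size** by Geyer's initial monotone positive
  sequence estimator.
- **Simultaneous credible bands**: mean ± $q \cdot$ pointwise sd with
  $q$ the empirical quantile of the maximum standardised absolute
  deviation over the grid, so the nominal fraction of posterior curves
  lies entirely inside the band.

## Synthetic survey generator

Real DHS microdata cannot be shipped, so the generator emulates a
two-wave child survey at the published scale (7 936 and 17 916 children)
over a configurable lattice of districts with rook adjacency:

- Continuous covariates are truncated normals whose *underlying*
  location is solved numerically (Brent root-finding on the truncated
  mean) so that the **truncated** mean hits the target — naive
  redraw-truncation would bias, e.g., mother's age at birth by +0.7
  years.
- Counts (vaccinations, birth order) are shifted Poisson; binary and
  proportion covariates match target rates.
- A latent household factor (loading 0.4 on urbanicity) links wealth,
  maternal education and urban residence; the asset index is the first
  principal component of eight binary asset indicators
  (Filmer–Pritchett), oriented and standardised.
- Cluster (PSU) coordinates are displaced as in DHS releases: up to
  2 km urban, 5 km rural, with 1% of rural clusters up to 10 km.
- True effects: smooth functions for the mean, a smooth zero-mean
  spatial field, and heteroscedastic log-scale effects of maternal
  education and vaccinations. All effects are centred per wave so the
  wave mean of HAZ equals its target (−1.59 / −1.47).
- The log-scale effect magnitudes (sd of $\log\sigma \approx 0.3$) were
  fixed *a priori* so that the DIC advantage of the location-scale
  model over the means-only model at full sample size matches the order
  observed in comparable survey analyses; they were not adjusted after
  seeing test results.
- A `GroundTruth` object records every true function, field and
  centering shift, and exports to JSON for validation.

Scope and limits: the generator matches first and second moments,
cross-correlations of the wealth/education/urban block, cluster
geography and effect shapes — it does not attempt to reproduce
higher-order interactions, non-response patterns or measurement error
of a real survey.

## Numerical choices

- Design points exactly on the upper boundary knot are nudged inside by
  a relative $10^{-12}$ so the last B-spline keeps partition of unity.
- All Gaussian draws go through Cholesky factors of precision matrices;
  singular precisions raise informative errors naming the block.
- Non-finite predictors abort the chain with the offending state dumped
  in the exception message.
- Every random quantity derives from a single user seed
  (all derived seeds < 2^31).

## Problem sizes used in the checked examples

The statistical test suite uses reduced but honest problem sizes chosen
for power-per-second: e.g. smooth recovery at n = 2 000 over 20
replicates, spatial recovery on a 5×5 lattice with 50 children per
district, model selection at n = 800 per replicate over 20 seeds, and
generator calibration at the full n = 17 916. Chains in these checks
are shortened (hundreds of iterations) because conjugate Gibbs and
near-independence IWLS-MH mix fast; the defaults for real analyses are
deliberately much longer.
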