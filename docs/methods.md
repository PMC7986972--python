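# Methods

## Model

`dismap` fits a Poisson hierarchical model to directly age-standardized
county counts for two population groups. The observation for county `i`
and group `r` is the age-adjusted count `y*_ir = Σ_a π_a y_iar`, a
standard-population weighted sum of the age-specific counts. Because the
weights are proportions, `y*` is generally non-integer; the likelihood
therefore uses the continuous Poisson kernel
`y* log(nλ) − nλ − logΓ(y* + 1)`, which coincides with the ordinary
Poisson log-mass at integer `y*`. An optional rounding mode
(`age_adjust_counts(..., round_adjusted=True)`) produces integer counts
for comparison with integer-only Poisson software; the default keeps the
weighted sum exactly as defined.

The log-rate is linear in a group indicator `x1`, a binary county
deprivation indicator `x2` (1 = ADI below the lower 20th-percentile
threshold, i.e. the *least* disadvantaged quintile), their interaction,
an exchangeable county-by-group effect `θ_ir ~ N(0, τ_h)`, and a
group-specific intrinsic CAR field `φ_·r` on the county border graph.
The interaction lets the group disparity differ between deprivation
strata. Default priors are flat on the intercept, N(0, 1000) on the
remaining fixed effects, and Uniform(0, 100) on each random-effect
standard deviation; `PriorConfig` swaps in a half-normal SD family for
sensitivity reruns.

### ICAR parameterization and identifiability

The intrinsic CAR log-density is used in its pairwise form
`−(1/2τ) Σ_{i~j} (φ_i − φ_j)²`, so `τ` is a variance-like scale: larger
`τ` permits rougher fields. The density is improper — constant shifts
within each connected component are free — so each group's field is
recentred to sum to zero (per component) after every sweep, the
convention of standard CAR samplers, with the free intercept absorbing
the level. Two consequences are handled explicitly:

* `log_prior` exposes the pairwise kernel only (it is a kernel, defined
  up to additive constants), but the *conditional* used to update the CAR
  scale includes the `τ^{−rank/2}` normalizing factor, with
  rank = counties − connected components. Without it the kernel is flat
  in `τ` along that direction and the scale drifts to its prior bound.
* The SD parameters are updated on the log scale, with the
  `d(sd)/d(log sd)` Jacobian in the acceptance ratio and explicit
  rejection outside the uniform support.

## Sampler

Metropolis-within-Gibbs, per sweep: each active fixed effect by scalar
random walk; all `θ_ir` in one vectorized elementwise Metropolis step
(their full conditionals are mutually independent); `φ` by elementwise
Metropolis over greedy graph-coloring classes so no two neighbours update
simultaneously; recentring; then the three SDs. Proposal scales adapt
toward 0.44 acceptance in batches of 50 sweeps during burn-in only and
are frozen afterwards, preserving the stationary distribution. Chains
initialize at the fixed-effects Poisson MLE (statsmodels GLM with offset
`log n`; a closed-form crude-rate intercept is the fallback when the GLM
cannot be fit), `θ = φ = 0`, SDs 0.5. Chain `c` uses an independent RNG
stream seeded by `(base_seed, c)`, making every run bit-reproducible.

The default protocol mirrors common practice for these strongly
autocorrelated models: 3 chains, thin 50, 20,000 retained per chain
(60,000 total). Tests and the bundled examples use desk-scale protocols
(3 chains × 600–800 burn-in and 1,500–4,000 retained sweeps, thin 1–2),
which the oracle checks below show are sufficient at those problem sizes.
Retained sweeps are exactly `burn_in + k·thin`, `k = 1, 2, …`.

Convergence is monitored with the classic (non-split) Gelman–Rubin
between/within variance ratio, floored at 1 so identical chains score
exactly 1.0. The rank-normalized split variant was deliberately not used:
its estimate drops below 1 when between-chain variance vanishes, which
breaks the `≥ 1` contract of this diagnostic.

## Estimands and DIC

Rate-ratio functionals (overall `λ̄·1/λ̄·0` with population-weighted group
means, county `λ_i1/λ_i0`, within-group `λ_i1/λ̄·1`) are computed per
retained draw and then summarized — never as ratios of summaries — with
equal-tailed 2.5/97.5% intervals by linear-interpolation quantiles. A
county is flagged when its interval's upper endpoint is below 1. Note the
overall ratio of group-specific *population-weighted* mean rates is not 1
merely because the two groups share a rate surface; it is 1 when the
shared surface is constant or the groups' county weightings coincide.

The heterogeneity surface is reported both as `mean(exp(θ+φ))` (labeled
default) and `exp(mean(θ+φ))`; the two differ by the lognormal
convexity factor, and map legends in the field are ambiguous between them.

DIC uses the cell-level log-rates as the focus: `D̄` is the mean posterior
deviance (−2 × log-likelihood), `D̂` the deviance at the posterior mean of
`log λ_ir`, `pD = D̄ − D̂`, `DIC = D̄ + pD`. This focus matches
disease-mapping practice when the smoothed surfaces are themselves of
interest. Negative `pD` is reported with a warning, not an error.
Differences ≤ 2 between models are reported as "no preference".

## Synthetic data generator

The generator draws from exactly the structure the model assumes, on the
packaged New Mexico 33-county border graph by default: ADI scores
~ N(110, 20²) (classified so 7 of 33 counties land in the lower quintile
when scores are distinct), `θ ~ N(0, sd_h²)`, ICAR fields sampled on the
sum-to-zero subspace via the eigendecomposition of the graph Laplacian
(covariance `τ L⁺`), and Poisson age-stratified counts. Default
parameters put the region in the regime the model is designed for:
baseline log-rate −7.0 per at-risk woman over a 10-year window, focal
disparity `β1 = log 0.384`, deprivation effect 0.229, interaction −0.303,
SDs (0.07, 0.143, 0.567), and at-risk denominators of 11,175 reference /
2,274 focal women per county (uniform across counties, matching the
region's average county sizes).

Because `λ` is the rate of the *age-adjusted* count, the age-split
shares are normalized so the standard-weighted expectation of `y*` equals
`n λ` exactly (`Σ_a π_a s_a = 1`); the raw age-summed counts are then
Poisson with mean `n λ Σ_a s_a (> n λ)`, as in real data where adjusted
counts are smaller than raw ones. The age profile rises steeply from the
teens to a plateau past 60, mimicking breast-cancer incidence.

What the generator does *not* emulate: registry artifacts (delayed
reporting, county misassignment, race misclassification), skewed county
population sizes, secular time trends, and any misspecification of the
log-linear form. Passing recovery tests therefore demonstrate the
correctness and calibration of the inference machinery under the model's
own assumptions, not robustness to violations of them.

## Verification strategy and problem sizes

* **Conjugate oracle** — intercept-only model on one cell (y* = 50,
  n = 1000, flat prior): exp(β0) is exactly Gamma(50, 1000); the sampler's
  mean and variance agree within 3 batch-means Monte-Carlo SEs at 10,000
  retained draws.
* **Grid oracle** — 3-county, 2-parameter reduced model: posterior mean
  of β1 agrees with dense 2-D numerical integration within 0.02.
* **Recovery** — 50 replicates at n = 100,000 per cell with modest
  random-effect SDs (0.05/0.1/0.1): 95% intervals cover each true β in
  44–50 of 50 replicates (binomial tolerance), and the posterior mean
  overall rate ratio is within 0.05 of each replicate's realized truth.
* **ICAR** — the pairwise kernel equals the dense Laplacian quadratic
  form on random graphs up to 8 nodes; sampled field covariance matches
  `τ L⁺` within 5% at 10,000 draws.
* **DIC** — pD = 0 for a degenerate posterior; pD ≈ 4 (± 0.5) for the
  4-parameter fixed-effects model at large n.

## Known limitations

* Recentring `φ` after Metropolis updates is the standard approximate
  treatment of the ICAR's improper direction; it is exact only in the
  limit where the intercept re-equilibrates, which the oracle and
  recovery checks confirm is adequate here.
* The packaged New Mexico adjacency was compiled from the county border
  map; corner-touch conventions can differ between published adjacency
  listings by a few edges.
* Zero at-risk populations are rejected (the offset `log n` is
  undefined), so regions with empty strata must be pre-aggregated.
* The sampler is a plain random-walk scheme; for much larger regions
  (hundreds of areas) gradient-based samplers would mix better.
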