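# dismap

Bayesian disease mapping of county-level incidence disparities between two
population groups.

## The problem

Comparing disease incidence between a small focal population and a large
reference population at the county level runs into the small-area
estimation problem: many counties contribute a handful of cases, so raw
age-adjusted rate ratios are wildly unstable. `dismap` implements a
BYM-style Bayesian Poisson hierarchical model that borrows strength
globally (exchangeable county heterogeneity) and locally (spatial fields
on the county border graph) to produce stable county-level and overall
rate-ratio estimates, together with everything needed to run the analysis
end to end with no external data: file readers, direct age
standardization, an adaptive Metropolis-within-Gibbs sampler, rate-ratio
estimands, DIC model comparison, and a synthetic study-region generator
with recorded ground truth. The packaged default study region is New
Mexico's 33 counties (border-sharing adjacency included).

## The model

For county `i` and group `r` (x1 = 1 for the focal group), the
age-adjusted count `y*_ir = Σ_a π_a y_iar` (standard-population weights
π_a over fifteen 5-year age groups) is modelled as

```
y*_ir ~ Poisson(n_ir λ_ir)
log λ_ir = β0 + β1 x1 + β2 x2 + β3 x1 x2 + θ_ir + φ_ir
```

where `n_ir` is the population at risk, `x2` flags counties in the lower
20th percentile of an Area Deprivation Index (ADI; higher = more
disadvantaged), `θ_ir ~ N(0, τ_h)` captures over-dispersion, and `φ_·r`
is an intrinsic conditional autoregressive (ICAR) field per group —
`CAR(τ_b)` for the reference group, `CAR(τ_c)` for the focal group — over
the shared-border adjacency graph. Priors: flat on β0, N(0, 1000) on
β1–β3, Uniform(0, 100) on each standard deviation. Inference is by
Metropolis-within-Gibbs (3 chains, thinned; 60,000 retained draws under
the default protocol) and the reported estimands are the posterior
distributions of

* the overall rate ratio `λ̄·1/λ̄·0` with `λ̄·r = Σ_i n_ir λ_ir / Σ_i n_ir`,
* county rate ratios `λ_i1/λ_i0`, and
* within-focal-group ratios `λ_i1/λ̄·1`,

with equal-tailed 95% credible intervals; a county shows a significant
deficit when its interval lies entirely below 1.

## Worked example

```python
import numpy as np
from dismap import (ChainConfig, GeneratorConfig, PriorConfig, fit,
                    generate, overall_rate_ratio_draws, summarize)

dataset, truth = generate(GeneratorConfig(seed=11, at_risk=(100_000, 100_000),
                                          sd_h=0.05, sd_b=0.1, sd_c=0.1))
samples = fit(dataset, PriorConfig(),
              ChainConfig(n_chains=3, burn_in=600, n_iter=2000, thin=1,
                          base_seed=5))
rr = summarize(overall_rate_ratio_draws(samples, dataset=dataset))
print(f"true RR {truth.overall_rate_ratio:.3f}")
print(f"posterior RR {rr.mean:.3f} (95% CrI {rr.lower:.3f}-{rr.upper:.3f})")
```

prints

```
true RR 0.360
posterior RR 0.356 (95% CrI 0.333-0.379)
```

— the generator drew a region whose realized overall focal/reference rate
ratio is 0.360, and the fitted posterior recovers it with a tight interval
because the synthetic populations are large.

The same pipeline is available from the shell:

```
dismap simulate --seed 1 --out data/
dismap fit data/ --seed 2 --out runs/full --model full
dismap fit data/ --seed 2 --out runs/reduced --model no-interaction
dismap summarize runs/full --out tables/
dismap compare runs/full runs/reduced
```

`summarize` writes a parameter table (posterior mean, SD, 95% interval for
β's, SDs and the overall rate ratio), a per-county rate-ratio table with
ADI quintile labels, and the exponentiated heterogeneity surfaces
`exp(θ+φ)`; `compare` applies the DIC rule that differences greater than
2 express a model preference.

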