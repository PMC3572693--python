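# critwin

Identification of critical gestational windows of ambient ozone exposure for
low birth weight, via a Bayesian temporal probit regression, with
nearest-source exposure assignment across three kinds of pollution products.

## Who this is for

Environmental epidemiologists asking *when* during pregnancy an exposure
matters, not just whether it does. Trimester-average regressions blur the
answer; entering all ~44 weekly exposures jointly destroys it through
multicollinearity (weekly ambient series are strongly autocorrelated, so the
weekly effect estimates have inflated, sign-unstable uncertainty). The model
here keeps weekly resolution while controlling that inflation with a
temporally correlated prior on the weekly effects.

A second question the package addresses: what happens to the risk assessment
when the exposure is taken from a sparse monitor network (observed but
distant), a complete deterministic chemistry-model grid (close but biased),
or a dense statistically calibrated product (close and calibrated)? The
pipeline assigns exposures under all three regimes from one cohort so the
resulting window estimates can be compared directly.

## The model

For term birth $i$ (gestational age $ga_i \in [37, 44]$ completed weeks)
with low-birth-weight indicator $Y_i$ (birth weight < 2,500 g):

$$Y_i \mid p_i \sim \text{Bernoulli}(p_i), \qquad
\Phi^{-1}(p_i) = x_i^\top \beta + \sum_{j=1}^{ga_i} z_{ij}\,\theta_j,$$

where $x_i$ holds the maternal/seasonal covariates (gestational age, season,
sex, parity, maternal age group, race/ethnicity, education, birth year, and
4-df cubic B-splines in birth-date temperature and dewpoint; $p = 29$
columns) and $z_{ij}$ is the standardized average ozone during pregnancy
week $j$, taken from the nearest active source each day. The weekly effects
get a smoothing prior

$$\theta \sim \mathrm{MVN}\!\left(0,\ \sigma^2_\theta\,\Sigma(\phi)\right),
\qquad \Sigma(\phi)_{jk} = e^{-\phi\,|j-k|},$$

with $\phi \sim \mathrm{Uniform}(0.0001, 3)$,
$\sigma^2_\theta \sim \mathrm{IG}(3, 2)$, and diffuse independent normal
priors on $\beta$. Fitting is by Gibbs sampling with truncated-normal latent
augmentation and a Metropolis step for $\phi$. Three variants share the
engine: the smoothed weekly model (model 1), a trimester-average model
(model 2), and a naive weekly model with independent diffuse priors
(model 3). Variants are compared by average credible-interval width and by
DIC with its effective-parameter count $p_D$.

Births with no active source within **8.49 km** (the half-diagonal of a
12 km grid cell, 5.28 miles) on some pregnancy day are excluded; complete
grid/dense products exclude nobody.

Because real birth registries are confidential, the package ships a
first-class synthetic generator (`critwin.synthetic`) that emulates the data
structure the analysis assumes: ~2.3% prevalence among term births, seasonal
+ AR(1) daily maximum 8-hour ozone (ppm) with spatially correlated
innovations, three co-registered source layouts whose nearest-source
distances order dense < grid < monitor, and outcomes generated forward from
the probit model with a true elevated-effect window at weeks 20–23.

## Worked example

```python
from critwin import (GeneratorConfig, McmcConfig, PriorSpec,
                     build_design, build_exposure_block, build_exposure_matrix,
                     eligibility_filter, gen_cohort, gen_outcomes,
                     gen_ozone_panel, gen_sources, identify_windows,
                     run_mcmc, summarize_windows)

cfg = GeneratorConfig(seed=1)                      # 10,000 births, dense metric
sources = gen_sources(cfg, regimes=("dense",))
panel = gen_ozone_panel(sources, cfg)
cohort, _ = eligibility_filter(gen_cohort(cfg), sources)

exposure = build_exposure_matrix(cohort, sources, panel)
design = build_design(cohort)
cohort, truth = gen_outcomes(cohort, exposure.values, design.matrix, cfg)
print(f"births: {len(cohort)}, LBW prevalence: {cohort['lbw'].mean():.3f}")

block = build_exposure_block(exposure, "weekly_structured", max_week=44)
draws = run_mcmc(cohort["lbw"].to_numpy(), design.matrix, block.matrix,
                 PriorSpec(), McmcConfig.test_profile(seed=2),
                 week_ids=block.weeks)
windows = summarize_windows(draws)
print(f"average 95% interval width: {windows.average_width:.3f}")
for run in identify_windows(windows):
    print(f"window: weeks {run.start}-{run.end}, sign {run.sign:+d}")
```

Output:

```
births: 10000, LBW prevalence: 0.021
average 95% interval width: 0.121
window: weeks 20-24, sign +1
window: weeks 40-40, sign +1
```

The generator planted positive effects in weeks 20–23; the fitted model
flags a positive window covering weeks 20–24 (smoothing can extend a run by
a neighbouring week, and isolated single-week flags such as week 40 here are
the ~5% false positives a 95%-interval rule produces across ~44 weeks). The
average interval width (0.121 per-SD probit units) is the headline precision
statistic used to compare exposure metrics.

There is also a CLI for configured, reproducible runs:

```sh
critwin run --seed 1 --metric dense --model 1 --profile test --outdir run1
```

writes `births.csv`, `exposure_dense.csv`, `design_dense.csv`,
`draws_*.csv`, `windows.csv`, fit metrics and a manifest with config hash
and stage timings into `run1/`.

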