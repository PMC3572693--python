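# Methods

This note documents the statistical model, the synthetic data-generating
process, the numerical choices, and the limits of what the test suite shows.

## Outcome model

Low birth weight (< 2,500 g) among term singleton births (37–44 completed
gestational weeks) is modelled as conditionally independent Bernoulli with a
probit link:

    Phi^{-1}(p_i) = x_i' beta + sum_{j=1}^{ga_i} z_ij theta_j.

The sum runs only to the gestational age of birth *i*, so exposure after
delivery can never influence its outcome; operationally the exposure matrix
stores exact zeros in weeks beyond `ga_i` and the validity mask guarantees
they stay zero through every transformation.

`x_i` (p = 29): intercept; gestational age (linear, weeks — a single
coefficient suffices for a term-birth cohort); season of birth (vs winter);
sex (female vs male); parity (1, 2+ vs none); maternal age group (five
contrasts vs 30–34); race/ethnicity (vs NH-white); education (vs <HS);
birth year (vs first year); and cubic B-spline bases with four degrees of
freedom in the region-wide temperature and dewpoint on the birth date.
Spline knots: boundary knots at the observed min/max, one interior knot at
the median (the conventional choice when only the degrees of freedom are
fixed); the first column of the intercept-bearing basis is dropped, matching
R's `bs(x, df = 4)`.

`z_ij` is the average of the daily maximum 8-hour ozone (ppm) at the
nearest active source over pregnancy week *j* (the *j*-th 7-day block after
conception; conception day = birth day − 7·ga). Pregnancy-week blocks, not
ISO calendar weeks, are used because the effect index in the model is the
week *of pregnancy*. Weekly values are standardized with one pooled
center/scale over all valid person-weeks, so "a one-SD increase in weekly
ozone" means the same thing in every week; per-week scaling is available as
an option. Standardization is done within each metric run (each product has
its own scale).

## Exposure assignment and eligibility

Each pregnancy day is matched to the closest source active that day
(planar Euclidean distance in km; ties broken by smallest source id for
deterministic reruns). A birth is eligible only if **every** pregnancy day
has an active source within 8.49 km; the exclusion log records the first
failing day. The radius is the half-diagonal of a 12 km × 12 km grid cell
(12·√2/2 = 8.4853 → printed as 8.49 km / 5.28 miles) — the farthest a
residence can sit from the center of the grid cell containing it, which is
why complete grid and dense products exclude nobody. The default is the
printed 8.49, not √72.

Trimester averages (model 2) use weeks 1–13 / 14–26 / 27–ga. The
boundaries are the conventional clinical split; nothing in the method
depends on them beyond bookkeeping.

## Priors and sampling

* beta: independent N(0, 1000) — "large fixed variance" made concrete;
  with n in the thousands the likelihood dominates entirely.
* theta (model 1): MVN(0, sigma2 · Sigma(phi)), Sigma(phi)_jk =
  exp(−phi·|j−k|). Small phi → near-common effect across weeks; phi = 3 →
  correlation e^−3 ≈ 0.05 between adjacent weeks, essentially independent.
* phi ~ Uniform(0.0001, 3); sigma2 ~ Inverse-Gamma(3, 2) (conjugate).
* Models 2 and 3 give their exposure coefficients independent N(0, 1000)
  priors and skip the sigma2/phi updates.

Sampling is systematic-scan Gibbs: latents → beta → theta → sigma2 → phi.

* **Latents**: w_i ~ N(eta_i, 1) truncated by the outcome sign, drawn by
  inverse CDF in log space (`log_ndtr` + `ndtri_exp`), which stays exact and
  finite however far the truncation point sits in the tail — no rejection
  loops that can stall.
* **beta, theta**: conjugate MVN draws from the posterior precision via
  Cholesky factorization and triangular solves; no explicit inverses.
* **sigma2**: IG(3 + g/2, 2 + theta' Sigma^{-1} theta / 2).
* **phi**: random-walk Metropolis on logit((phi−l)/(u−l)) with the Jacobian
  correction; the proposal SD (default 0.6) adapts by ×0.7 / ×1.4 steps
  toward a 0.2–0.5 acceptance rate during burn-in and is frozen afterwards.
* Initialization: beta = theta = 0, sigma2 = 1 (prior mean), phi = 1.5
  (interval midpoint); divergence guard aborts with the iteration index if
  the state goes non-finite.
* Profiles: the default configuration is 50,000 burn-in + 50,000 kept
  draws, thin 1; the `test` profile used throughout the suite and the
  acceptance script is 2,000 + 2,000, which the oracle comparisons below
  show is ample for the posterior-summary precision needed at desk scale.

Weeks with zero valid observations are dropped before fitting (their effect
is not estimable); truncating the *display* of late weeks (e.g. to week 40
for the naive model, whose final-week intervals explode) is a reporting
option and never affects the fit.

## Summaries and model comparison

Per-week posterior medians with equal-tailed 95% intervals; a week is
"significant" when its interval excludes zero, and maximal runs of
consecutive significant weeks of common sign form the reported windows.
The average interval width across weeks is the precision statistic used for
cross-metric comparison, alongside Jaccard overlap of significant-week sets
and per-week median differences against a reference metric.

DIC = D̄ + p_D with p_D = D̄ − D̂; the plug-in D̂ evaluates the deviance at
the posterior means of (beta, theta) — the classical form. Probabilities
are clamped to [1e−12, 1−1e−12] before logs. Monte-Carlo standard errors of
posterior means use batch means with ≈ √n batches.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* the analysis depends on:

* **Cohort**: configurable categorical covariate frequencies (defaults
  loosely matching a Hispanic-majority South Texas birth population),
  gestational ages on 37–44, residences clustered around two population
  centers on a 120 km square, birth dates uniform over the days for which
  the whole pregnancy fits in 2001–2004. Temperature/dewpoint are one
  region-wide seasonal daily series shared by all births on a day.
* **Ozone** (ppm, daily max 8-hour): mean 0.040, seasonal amplitude 0.010
  (summer peak), AR(1) deviations (coefficient 0.7, innovation SD 0.005)
  with exponential spatial correlation (range 100 km), clipped to (0, 0.5).
  These values put weekly averages around 0.03–0.06 ppm, the realistic band
  for the regulatory metric.
* **Three metric regimes** from one latent field: monitors (6 by default,
  near the population centers, optional per-day inactivity) report the
  latent field; the 12 km grid reports a 7-day-smoothed, biased transform
  (×1.10 plus a ±0.003 ppm smooth spatial bias) emulating deterministic-
  model error; the dense lattice (2 km) reports the latent field plus
  0.001 ppm calibration noise. Median nearest-source distances are ordered
  dense < grid < monitor in every realization, mirroring the ordering of
  real monitor / grid / census-tract products.
* **Outcomes**: generated forward through the probit model with true
  elevated effects in weeks 20–23 and the intercept calibrated by bisection
  so the marginal rate hits the 2.3% term-birth prevalence target. The
  default per-week window effect is 0.15 per SD: the analysis is run at
  10,000 births rather than the ~37,000 of a full regional registry, and
  0.08·√(37,331/10,000) ≈ 0.15 keeps the information content of the window
  comparable at desk scale.

What it does **not** emulate: real geography (census tracts, shapefiles,
road networks), the actual downscaler model (the dense regime *mimics* a
calibrated product; it is not a fitted calibration), residential mobility,
covariate-outcome confounding structure (true covariate effects default to
zero and are configurable), or registry artifacts such as missing
demographics. Passing tests therefore demonstrate that the *method* behaves
correctly on data with the assumed statistical structure — not that any
particular real-world effect estimate is right.

## Verification strategy

* Closed-form pieces (radius geometry, correlation matrix, deviance,
  DIC identities, trimester/weekly arithmetic) are checked against
  independent hand or brute-force computation.
* The B-spline basis is checked against an independent Cox–de Boor
  recursion, including partition of unity at the boundaries.
* Each full conditional is checked against its analytic distribution
  (KS test for sigma2; moments for latents and conjugate draws; a 1-d
  grid-posterior oracle for phi).
* The whole sampler is checked against a dense 4-d grid-quadrature oracle
  on a 60-observation instance, within 3 Monte-Carlo standard errors.
* Frequentist calibration at the null (theta = 0) is checked over 100
  replicate fits with the diffuse-prior variant: the structured prior
  *over*-covers zero at the null by design (that is what shrinkage does),
  so the diffuse variant is the right instrument for a 95%-coverage check.
* Window recovery is checked end-to-end at 10,000 births and 2.3%
  prevalence: the fitted model must flag a positive window containing weeks
  20–22.
* Multicollinearity control is checked by replication: on AR(0.9) weekly
  exposures the structured prior must yield narrower average intervals and
  smaller p_D than the naive diffuse fit.

## Known limitations

* Single-chain inference with batch-means MC errors; no multi-chain R-hat
  machinery (trace exports allow external diagnostics).
* The phi posterior is weakly identified when the weekly-effect vector is
  short or near zero; at the null it tends toward the lower bound (maximal
  smoothing), which is the intended regularization behaviour, not a defect.
* Probit only; no logit link, no spatial random effects, no WAIC/LOO.
* Planar coordinates throughout; geographic inputs must be projected first.
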