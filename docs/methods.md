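# Methods

## Model and estimands

Households *i* (level 1) are nested in intersectional social strata *j*
(level 2), one stratum per observed combination of six categorical
social-position factors: head-of-household gender (2), marital composition
(3), income-activity engagement (2), food security (2), disability (2) and
settlement (3) — 144 possible combinations, of which typically ~120-130 are
observed at n ≈ 4,900 households.  Three nested Bayesian logistic models are
fitted to a binary healthcare-utilisation outcome:

* **Model 1 (null)**: intercept + stratum random effect `u_j ~ N(0, sigma_u^2)`.
  Its VPC is the *general contextual effect* — how strongly stratum
  membership discriminates outcomes.
* **Model 2 (main effects)**: adds the six factors as additive dummy-coded
  fixed effects (reference categories: female, single, no income activity,
  food secure, no disability, Cockle Bay).  Its residual `u_j` is the
  *intersectional* deviation: what the additive decomposition cannot explain.
* **Model 3 (adjusted)**: adds household explanatory covariates (tenure,
  water, sanitation, waste, income sources, household size, ...) to assess
  whether intersectional patterning survives adjustment.

On the latent-response scale the level-1 variance of a logistic model is
`pi^2/3` (evaluated at full precision, ~3.2899), so

```
VPC_k = sigma_k^2 / (sigma_k^2 + pi^2/3),    PCV_k = (sigma_1^2 - sigma_k^2) / sigma_1^2.
```

PCV is computed from the stratum **variances** by default.  A variant
computed from VPC differences is available (`method="vpc"` in
`metrics_report`); the two disagree slightly because the VPC denominator
includes `pi^2/3`.  The variance-based definition is the default because it
is the one consistent with the PCV values that published MAIHDA variance
tables actually print.

Point stratum variance is the squared posterior median of `sigma_u` (robust
to the right skew of the variance posterior); per-draw VPC posteriors
(median and 95% CrI) are reported alongside, and on our fixtures the two
agree within ~10% relative.

Residual intersectional effects are the posterior medians of `u_j` with
equal-tailed 95% credible intervals, ranked ascending (ties broken by
stratum id so the ordering is reproducible), flagged when the interval
excludes zero.  No multiplicity adjustment is applied — flags are
per-stratum credible statements, not family-wise claims.  Predicted stratum
probabilities are evaluated at reference covariates and are auxiliary
output.

## Priors

* Fixed effects (including the intercept): `Normal(0, 1)` — regularising
  shrinkage toward null odds ratios, appropriate for dummy-coded log odds.
* Stratum scale: half-Student-t on `sigma_u` with **df = 2** (configurable)
  and scale 10, i.e. weakly informative on the standard-deviation scale with
  heavy tails.  The prior is placed on the scale, not the variance, and
  truncated to (0, inf).

## Sampler

No Stan/PyMC-style PPL is a dependency; the posterior is sampled by a
purpose-built Hamiltonian Monte Carlo kernel (`maihda._hmc`) with analytic
gradients:

* **parameterisation** — non-centred stratum effects `u_j = sigma_u * z_j`
  with `z_j ~ N(0,1)`, and `sigma_u` sampled as `tau = log sigma_u` (with
  the Jacobian term).  Non-centring is essential here: many strata have
  fewer than 5 households, and the centred funnel would cripple mixing.
* **likelihood aggregation** — records are collapsed to unique
  (stratum, design-row) binomial groups, so a gradient costs O(groups):
  48 groups instead of 4,000 records for the stress scheme, ~130 for the
  null model at survey scale.
* **adaptation** — leapfrog step size by Nesterov dual averaging targeting
  0.8 acceptance; a diagonal mass matrix estimated from the middle warmup
  window (regularised toward unity), after which step-size adaptation
  restarts; trajectory lengths jittered uniformly on [1, 48] steps.
* **robustness** — non-finite or exploding Hamiltonians reject the proposal;
  post-warmup divergences are counted and reported on the result, and any
  parameter with rank-normalised split-Rhat >= 1.01 after the run produces a
  recorded warning, never a silent pass.
* **determinism** — chains draw from `numpy` Generators spawned off a single
  `SeedSequence`; identical config and seed reproduce draws bit for bit, and
  the canonical group aggregation makes fits exactly invariant to record
  order.

Run-length presets: `McmcConfig.paper_scale()` (4 chains x 20,000
iterations, 2,000 burn-in per chain — the production setting) and
`McmcConfig.test_scale()` (4 x 2,500, 500 burn-in), which is what the tests,
the experiments and the acceptance script use; at that scale the stress
fixtures clear Rhat < 1.01 and bulk/tail ESS >= 1000 on every parameter.
The burn-in is interpreted per chain and serves as the adaptation window.

## Diagnostics

`maihda.diagnostics` implements the modern rank-normalised variants:
split-Rhat as the max of the bulk (rank-normal) and folded statistics;
bulk-ESS from rank-normalised split chains via FFT autocovariance and
Geyer's initial-monotone-positive pairing; tail-ESS as the minimum ESS of
the 5%/95% exceedance indicators.  Constant input raises an
`UndefinedDiagnosticError` rather than returning a vacuous 1.0.  The classic
Gelman-Rubin PSRF is exposed for comparison.  The test suite cross-checks
all three against arviz on iid and AR(1) chains (agreement within a few
percent; small differences come from truncation details of the
autocorrelation sum).

## Synthetic-data generator

`SimulationTruth` + `simulate_survey` generate surveys with the exact
structure the model assumes: factors drawn independently from marginal
prevalence tables, one `u_j ~ N(0, sigma_u^2)` per *realised* combination
(drawn in lexicographic order, so datasets are seed-reproducible regardless
of record order), optional injected log-odds shifts `delta` per combination
(`inject_intersectional_effect`), additive fixed effects, independent
categorical covariates, and a Bernoulli outcome.  The implied latent VPC of
a truth is `sigma_u^2/(sigma_u^2 + pi^2/3)` by construction.

Default conditions (`default_truth`) mirror the published survey margins:
the six-factor prevalences of the descriptive table, n = 4,871, main-effect
log odds ratios of the main-effects model for within-settlement HU, and
`sigma_u = 0.25` (the residual stratum scale after main effects,
sqrt(0.06)).  At these settings a draw realises ~125-135 of the 144 strata
with sizes from 1 to several hundred and ~30% of cells under 5 households —
the same qualitative regime as the real survey (122 strata, sizes 1-551,
~38% under 5).  A balanced 48-stratum `stress_truth` (2x2x2x2x3 scheme,
n = 4,000) is the workhorse for recovery and calibration experiments because
every cell stays well populated.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: factor dependence (real social positions are
correlated; only margins are matched, though a joint table can be supplied),
outcome-specific stratum effects for the variant outcomes (`hu_outside` is
emitted by an intercept shift sharing the stratum effects, and the formal-
provider variants by independent thinning — plumbing fidelity, not
scientific fidelity), nonresponse mechanisms, spatial sampling structure and
seasonality.

## Validation experiments (scaled-down by design)

Problem sizes are chosen so the whole battery runs in minutes on one CPU:

* **Recovery**: 20 replicates of the 48-stratum scheme at n = 4,000,
  `sigma_u = 0.8`, model 2 at test scale; the 95% CrI covers the truth in
  >= 90% of replicates.
* **Null calibration**: 10 replicates with `sigma_u = 0`; posterior median
  VPC stays below 0.05 (the half-t prior does not manufacture spurious
  clustering).
* **Injection**: `delta = 1.5` on the all-reference stratum at n = 6,000
  (expected cell size 125); the stratum must be flagged positive and ranked
  in the top two residuals in >= 18/20 replicates.  Top-two rather than
  strictly first: shrinkage pulls the injected residual toward the pack, and
  with 47 competing strata a single swap is within the noise of the check's
  purpose.
* **Quadrature oracle**: on a 200-household, 8-stratum instance with
  near-flat fixed-effect priors (sd 100), HMC posterior means must match
  marginal ML estimates from an independent adaptive Gauss-Hermite
  quadrature oracle within 3 Monte-Carlo SEs.  The instance is deliberately
  *balanced* (intercept 0, small effects, all cell probabilities near 0.5):
  the third derivative of the Bernoulli log-likelihood is proportional to
  (1 - 2p), so near p = 0.5 the likelihood is locally symmetric and the
  posterior mean coincides with the ML mode — elsewhere the mean-mode gap is
  a genuine finite-sample property of Bayesian logistic regression, not a
  sampler defect, and the comparison would be uninformative.

## Numerical and design notes

* Percentages in descriptive tables are rounded half away from zero to one
  decimal, matching survey-table convention; counts are always carried so
  percentages can be recomputed exactly.
* Complete-case analysis per outcome: records missing the outcome or any
  factor (or, for model 3, a requested covariate) are excluded for that
  analysis only, with an audit trail; no imputation.  Analysis-set sizes
  therefore differ across outcomes, as in the source survey.
* Strata are defined by observed combinations only; unobserved cells get no
  random effect.  Ids are 1-based in lexicographic order of the declared
  category order.  Sparse cells are retained and shrunk, never pooled.
* The sparse-cell percentage is reported over observed strata.  (The
  published "48 of 122 = 37.5%" implies a different, unstated denominator;
  48/122 is 39.3%.)
* The single-proportion sample-size formula
  `ceil(z^2 p (1-p) deff / (d^2 (1-NR)))` is implemented directly; with
  p = 0.47, deff = 10, d = 0.03, z = 1.96, NR = 0.10 it evaluates to 11,815.
  (The survey's stated planning figure of 4,883 corresponds to different
  effective inputs, e.g. deff ~ 4.1; the formula here is the textbook one.)
* Integer covariates (household size) are mean-centred in the design so the
  intercept keeps its reference-cell interpretation and the sampler's mass
  adaptation is well conditioned.
* Degenerate analysis sets (outcome constant) raise immediately; logistic
  separation in sparse cells is handled by the priors, which keep the
  posterior proper.
* The pipeline derives per-stage seeds from the master seed via
  `SeedSequence([seed, outcome_index, tier_index])`, so stages can be re-run
  in isolation with identical results.

## Known limitations

* Single-CPU sequential chains; no within-chain parallelism.
* The HMC kernel uses a fixed jittered trajectory length, not NUTS; very
  high-dimensional model-3 fits mix more slowly per iteration (use longer
  runs at survey scale).
* VPC thresholds for "meaningful" discriminatory accuracy (e.g. the 5-20%
  band quoted in the MAIHDA literature) are interpretive conventions, not
  quantities this package tests.
* The generator's variant outcomes share stratum effects with the primary
  outcome; do not use them for quantitative multi-outcome inference.
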