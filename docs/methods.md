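# Methods

This note records the models the package implements, the defaults it ships,
and the design choices made where the design was genuinely open. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic trial programmes

The generator (`comorbmeta.cohorts`) emulates the participant-level
structure of industry-sponsored phase 3/4 trial cohorts, per indication:

- **Age** is Normal(mean, SD) with indication-specific moments (e.g. the
  shipped diabetes profile uses 58.7 (SD 10) years); **sex** is Bernoulli
  with the profile's male fraction.
- **Comorbidity count** follows a four-bin distribution over {0, 1, 2, 3+}
  (diabetes default 18.6% / 31.3% / 26.3% / 23.8%). The aggregate 3+ mass is
  spread over counts 3..21 with a truncated geometric tail (decay 0.5 per
  unit by default), keeping high counts rare as in real trial populations
  where only the aggregate bin is reported.
- **Flags** for the 21 predefined long-term conditions are drawn without
  replacement conditional on the count — uniformly by default, or
  proportionally to per-condition allocation weights (exact Gumbel top-k
  sampling). Profiles that define "six commonest comorbidities" give those
  six the largest weights, which is what makes "commonest" well defined in
  synthetic data; the count always equals the flag sum by construction.
- **Biomarkers** (eGFR, BMI, FIB-4, haemoglobin, mid-BP) are independent
  normal or moment-matched lognormal draws on natural units. They are
  treated as measured quantities, not modelled from physiology.
- **Baseline outcome** is Normal and independent of covariates by default;
  a single correlation knob ties it to age when wanted. Joint distributions
  (age × comorbidity correlation, biomarker-comorbidity dependence) are
  *not* emulated — passing tests therefore demonstrate correctness of the
  estimation machinery under the stated generating model, not robustness to
  the full dependence structure of real cohorts.

Outcomes follow the stage-1 regression model exactly: a linear predictor
with main effects (intercept, baseline, age in 15-year units centred at the
cohort mean, sex) plus an arm term carrying the treatment effect and every
treatment-covariate interaction, with identity/Gaussian, log/Poisson, or
logit/Bernoulli response by outcome family. Biomarker interactions act on
cohort-standardised biomarkers so the generator's coefficients live on the
same scale the analysis estimates. Each trial consumes one seed stream split
by purpose (covariates vs outcome noise), so switching an interaction on
never perturbs the covariate draws; programmes are pure functions of
(config, seed).

## Stage 1: within-trial fits

Ordinary least squares for continuous outcomes, Poisson and logistic GLMs
otherwise (statsmodels), with the model-based (non-robust) covariance.
Complete-case per model. Single-sex trials drop the sex terms with a logged
notice rather than failing. Rank deficiency raises an error naming the
collinear columns; in multi-trial runs such failures are collected per
trial, not fatal. Logistic fits that separate fall back to a ridge-penalised
fit (L2 on all coefficients, inverse penalised Hessian as covariance) with a
warning — a small known bias is preferred to exporting unstable SEs.
Biomarker covariates are standardised per trial by default (a configurable
(center, scale) registry mirrors the 15-year age unit); age centering
defaults to the per-trial mean, which affects intercept-like terms only —
interaction slopes are translation invariant (tested).

## MCID standardisation

Continuous-outcome exports are divided by the registry MCID (covariance by
MCID²) and multiplied by −1 where higher scores are better, so positive
pooled interactions always mean attenuation of benefit in MCID multiples.
Count/binary exports pass through and pool on the log scale, reported
exponentiated, since ratios are already unit free. MCIDs are user-supplied
configuration with a provenance string per entry; the shipped example
registry carries the HbA1c value of 4 mmol/mol used in the worked example
plus conventional demo values for systolic BP (5 mmHg) and FEV1 (100 mL,
direction higher-better). Where two outcomes tie for "most common" in an
indication, the registry must name one explicitly; there is no automatic
tie-break.

## Stage 2: Bayesian pooling

Per (indication, comparison) group the standardised coefficient vectors are
modelled as `theta_t ~ MVN(mu + b_t, Sigma_t)` with `Sigma_t` fixed at the
exported within-trial covariance and `b_t ~ MVN(0, T)`. The selection rule
is random effects at 5 or more trials, fixed effects (`T = 0`) below, with
a sensitivity flag forcing random effects; the threshold is configurable.

Priors (exposed in `MCMCConfig`):

- `mu_j ~ Normal(0, 1)` in MCID units — MCID-scale interactions beyond ±1
  are clinically enormous, so this is weakly informative where it matters;
  oracle-comparison tests use a widened scale.
- between-trial SDs `tau_j ~ Half-Normal(0, 0.5)`;
- random-effect correlations: LKJ(2). The correlation prior is applied per
  canonical partial correlation of the Cholesky construction, which is
  exactly LKJ(2) for the dimensions the pipeline pools jointly (d ≤ 2:
  age+sex, or the univariate count) and an LKJ-like vine prior above that.

Sampling marginalises `b_t` analytically (`theta_t ~ MVN(mu, Sigma_t + T)`)
so the parameter count is independent of the number of trials, and runs
`emcee`'s ensemble sampler with differential-evolution moves (32 walkers,
4,000 retained draws each after 2,000 burn-in by default). Walkers are
treated as chains for split-R̂ and bulk-ESS diagnostics (arviz); the
convergence gate (R̂ ≤ 1.01, ESS ≥ 400, stricter than typically reported
for such models) raises instead of returning summaries. Fixed and random
effects share this sampler path; the analytic inverse-variance/GLS solution
exists only as an independent oracle in the test suite. Shrunken
trial-specific effects are computed from the conjugate conditional
`E[b_t | mu, T, theta_t] = T (T + Sigma_t)^{-1} (theta_t - mu)` averaged
over posterior draws. Replicated simulation tests (interval coverage of a
true interaction of 0.3 MCID units across 8-trial programmes; null
calibration across 5-trial programmes) run at reduced sizes — 250
participants per trial, 16 walkers, 1,000 retained draws — chosen as the
smallest budgets at which the Monte-Carlo summaries are stable.

## Predictive Student-t priors

For the comorbidity-count interaction only (continuous outcomes), a
three-level exchangeable hierarchy — trial within treatment comparison
within index condition, each level with its own Half-Normal(0, 0.5) SD and
a Normal(0, 1) grand mean — is fitted to the standardised estimates by the
same marginalised-likelihood ensemble approach. This is the minimal
hierarchy consistent with predicting an unobserved condition *and*
comparison; at least two conditions are required or the between-condition
variance is unidentifiable. Predictive samples draw a new condition effect
and a new comparison effect per posterior draw; whether a new trial-level
deviation is also integrated over is a flag (default: yes, so the samples
describe a future trial's interaction rather than a comparison-level mean).

Samples are summarised by a maximum-likelihood Student-t fit over
(location, log scale, log df), df bounded to [1, 200] because the
likelihood is nearly flat in df above ~50; fits at the bound are flagged
"normal-like". The fitter requires ≥1,000 samples with nonzero spread and
reports the t log-likelihood against a normal fit on the same data.

## Numerical notes and limitations

- Trial CSV tables are written with `%.17g` and read with round-trip float
  parsing, so programmes survive the text round trip bit-identically.
- Within-trial covariances are validated symmetric PSD (tolerance 1e-8) and
  `diag(vcov) = se²` to 1e-10 on every export.
- The ensemble sampler's hyperparameter support is bounded (log-SDs in
  (−30, 5)) to keep the batched linear algebra well conditioned; the
  half-normal priors place no appreciable mass outside.
- No survival outcomes, no within-trial missing-data modelling, no network
  meta-analysis across comparators, and no frequentist REML path (the GLS
  closed form is a test oracle only). Trial eligibility screening, dropout,
  and derivation of comorbidity flags from medication codes are out of
  scope — synthetic flags are generated directly.
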