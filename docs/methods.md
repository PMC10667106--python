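# Methods

## Scope and data model

The package analyses individual-level rows (one surveyed adult: study id,
sex, age in years, BMI in kg/m², FPG in mmol/L, HbA1c in NGSP %, previous
diagnosis and medication flags, pregnancy flag, measurement-round index)
grouped into studies with metadata (world region, mid-year, whether FPG
and HbA1c were measured in a laboratory or with a portable device, and
whether FPG came from capillary whole blood).  Diagnostic thresholds are
fixed at FPG ≥ 7.0 mmol/L and HbA1c ≥ 6.5 %.  Real pooled survey
databases with both biomarkers are access-restricted, so all testing and
the shipped results run on the synthetic generator below.

## Synthetic cohort generator

**Biomarker model.**  Within a study in region *r*, (log FPG, log HbA1c)
is bivariate normal.  Both biomarkers are strictly positive and
right-skewed, so the log scale keeps the correlation parameter
interpretable and values positive.  The mean vector is shifted by a shared
covariate risk score

  risk = β_sex·male + β_age·(age−50)/10 + β_bmi·(BMI−27)/5

(defaults 0.010, 0.022, 0.040 on the log-biomarker scale — small
multiplicative effects of the size seen in survey data), by a per-study
random effect u_j ~ N(0, 0.05²), and, for FPG, by an optional
region-specific sensitivity multiplier.  Region defaults (geometric means
5.3–5.6 mmol/L and 5.3–5.8 %, log-sds 0.18 and 0.13, correlations
0.51–0.76, BMI means 23.1–28.3 kg/m²) echo published regional summary
tables for this kind of pooled database: south Asia lower BMI and a much
larger undiagnosed share, sub-Saharan Africa the highest biomarker
correlation.  They are plausibility defaults, not estimates.

**Correlation semantics and calibration.**  The configured
`biomarker_correlation` is the quantity survey analyses report: the
Pearson correlation of (FPG, HbA1c) **among participants without a
previous diagnosis**.  Because the diagnosis mechanism preferentially
removes jointly-high observations, the observable undiagnosed correlation
is attenuated (~0.04–0.06) relative to the generating noise correlation.
The generator therefore solves for the latent correlation by bisection on
a fixed internally-seeded Monte-Carlo sample (n = 60,000, 18 bisection
steps, cached per region parameterization) so that the *observable*
within-study correlation matches the configured value.  The calibration
sets the study random effect to zero because a study's shared shift adds
no within-study variance.

**Diagnosis mechanism.**  Among rows in the diabetic range (either
biomarker at/above threshold), P(diagnosed) = logistic(a_r + 2·z), where z
is the standardized mean of the two log biomarkers and a_r is found by
bisection so the expected diagnosed fraction among the diabetic equals
the region's target (defaults 0.34 in south Asia to 0.70 in the
high-income western region).  Diagnosed participants carry a medication
flag with probability 0.8.  The real mechanism of who gets diagnosed is
unobserved; a logistic-in-glycemia rule captures the essential feature
that more severe glycemia is more likely to be already diagnosed.

**Ground truth.**  For every generated row the exact marginal and
conditional threshold-exceedance probabilities are recorded (normal CDF of
the latent means; conditionals use the standard bivariate-normal
conditional distribution given the realized other biomarker).  These are
the oracles for classification, prediction-equation and cross-validation
checks.

**Artifacts.**  Each row is independently assigned at most one artifact
(pregnancy 1 %, under-18 0.8 %, missing biomarker 1.5 %, implausible pair
0.2 % by default).  Implausible pairs place one biomarker near the
region's 99.9th percentile and the other near the 5th (e.g. FPG ≈ 28
mmol/L with HbA1c ≈ 5 %), guaranteeing the LOF filter has true positives
far outside the correlation structure.  Artifact rows are flagged in the
ground truth so distributional checks can exclude them.

**Direct regression simulators.**  Two additional simulators draw outcomes
straight from the downstream model structures with user-specified true
coefficients: a log-link binomial model with study random effects, and a
mixed-logistic prediction-equation cohort.  The latter by default
residualizes the drawn study random effects against the study-level design
columns (region, method) and rescales them to the requested variance:
with a finite number of studies, the realized mean random effect of one
region's studies is statistically inseparable from that region's fixed
effect, so orthogonalization lets recovery tests measure estimator error
rather than that information floor.  It can be disabled.

**What the generator does not emulate.**  Within-study sampling design
(simple random sampling is used), age- or sex-specific response rates,
assay drift over time, repeated measurements, and any dependence of BMI on
glycemic status.  Passing tests demonstrate correctness of the pipeline's
computations and estimators under a controlled data-generating process,
not epidemiological validity of any particular real-world estimate.

## Cleaning

Fixed, logged order: (1) exclusions — pregnant, age < 18, measurement
round > 1, missing diagnosis information, and (for biomarker analyses)
missing FPG/HbA1c; each excluded row records its first-triggered reason;
(2) plausible-range filter with closed intervals, defaults FPG
[2.5, 30] mmol/L and HbA1c [3, 18] % — wide enough that extreme but
physiologically possible single values (FPG 28, HbA1c 17) are left to the
joint filter; (3) capillary whole-blood glucose × 1.11 → plasma-equivalent
(the conventional factor; configurable), applied before the joint filter
so all pairs share a scale, and skipped for devices already reporting
plasma-equivalent values; (4) LOF filter on z-standardized (FPG, HbA1c)
with Euclidean distance, k = 100 neighbours (clipped to n−1): a point is
removed when its local reachability density is below half the average of
its neighbours' — algebraically LOF > 2, ties retained.  Standardization
prevents the mmol/L axis dominating the % axis.  The LOF computation uses
scikit-learn's `LocalOutlierFactor`; an independent O(n²) reference
implementation in the test suite confirms score agreement to 1e-9.

## Classification and prevalence

Previous diagnosis or glucose-lowering medication ⇒ *diagnosed*,
regardless of biomarker values.  Otherwise the ≥-inclusive threshold logic
yields isolated elevated FPG / isolated elevated HbA1c / both elevated /
no diabetes.  Crude prevalence uses all classified rows.
Age-standardized prevalence is the weighted mean of age-band-specific
proportions; the shipped standard is the WHO world standard population
aggregated onto bands 18–19, 20–29, …, 70–79, 80+ (5-year source bands
split pro rata), renormalized over 18+.  Empty bands renormalize the
weights over populated bands with a warning.  Regional tables standardize
within region; the pooled row standardizes over the pooled sample.  The
undiagnosed FPG–HbA1c correlation is Pearson by default (configurable to
rank).

## Log-binomial association models

Among screen-detected participants, three separate binary outcomes
(isolated FPG / isolated HbA1c / both) are regressed on: male sex, age/10
(as-is, so a 55-year-old contributes 5.5), BMI/5, region indicators
(high-income western reference), (mid-year − 2010)/5, per-study percent of
people with diabetes previously diagnosed /10 (computed from the full
study sample, before any biomarker subsetting), and portable-device
indicators for each biomarker.  Constant columns (e.g. no portable
studies) are dropped.  The model is log p = x′β + u_j with
u_j ~ N(0, σ_u²).

**Priors.**  β ~ N(0, sd 10) and σ_u ~ Uniform(0.01, 2.00).  A coefficient
prior of sd 0.01 — the literal alternative reading of the common
precision-0.01 parameterization of BUGS-family engines — would make
routinely observed PRs (e.g. 0.24, |β| ≈ 1.43 ≈ 143 sds) essentially
impossible a priori, so sd 10 is the default; the scale is configurable.

**Sampler.**  Adaptive random-walk Metropolis-within-Gibbs, 4 chains:
a joint multivariate proposal for β whose covariance starts at the inverse
Fisher information of the log-link Bernoulli model at the initial state
(capturing the strong intercept–covariate correlation induced by the
uncentered scalings) and adapts Haario-style during burn-in with
Robbins-Monro scale tuning; independent per-study scalar proposals for
u_j; and an exact Gibbs draw for σ_u² from its truncated inverse-gamma
conditional.  The p ≤ 1 constraint is enforced as zero likelihood: any
state with max_i x_i′β + u_{study(i)} ≥ 0 is rejected, so every retained
draw satisfies the constraint.  Defaults mirror the reporting convention
(4 chains, 5,000 burn-in, 12,500 retained per chain = 50,000 draws);
simulation checks use a reduced preset (4 × 1,000 burn-in / 2,000
retained), which the recovery suite shows is sufficient at its problem
sizes.  Convergence is summarized by split R-hat with threshold 1.05;
non-convergence flags the fit and warns, never silently passes.

**Summaries.**  Per covariate: posterior mean of exp(β), 2.5th/97.5th
percentile credible interval, and the posterior probability that a PR
whose posterior mean is above 1 is below 1 (and vice versa).

## Prediction equations

Nine registered specifications per direction (FPG→HbA1c and HbA1c→FPG),
all with a study random intercept: (1) biomarker only; (2) + sex + age;
(3) + method; (4) + region intercepts; (5) = 4 + BMI + region-specific
biomarker slope; (6) = 5 + sex-specific slope; (7) = 4 + region-specific
slope without BMI; (8) = 5 re-parameterized as per-region intercept and
slope (identical column span); (9) = 8 + sex-specific slope.  The exact
composition of the nine models in the source analysis is not fully
published; this registry is an explicit reconstruction consistent with the
stated constraints (models 5 and 8 include BMI and region-specific
biomarker terms; sex-interaction variants exist) and is configurable.

Age enters continuously and the biomarker linearly (no polynomial terms).
For numerical conditioning and interpretability the design centers the
biomarker at 5.5 (mmol/L or %), age at 50 years and BMI at 27 kg/m² —
fixed constants, so cross-validation folds share no data-dependent
scaling.  Intercepts therefore refer to a reference adult (female, age 50,
BMI 27, laboratory measurement, high-income western region) rather than
an extrapolated covariate origin.

**Fitting.**  Maximum approximate-marginal-likelihood: a joint penalized
Newton iteration on (β, u) — solved with a Schur complement so cost scales
with the number of fixed effects — alternating with a Laplace EM update
σ² ← mean_j(û_j² + v_j), v_j = (Σ_i w_i + 1/σ²)⁻¹, to the fixed point
(tolerance 1e-8, ≤ 200 outer iterations; failure to reach the fixed point
flags the fit).  The reported deviance is −2× the Laplace-approximate
marginal log-likelihood, a proper objective under which a richer nested
specification cannot be materially worse.  The fitter is deterministic;
agreement with lme4::glmer (fixed effects within 0.02, variance within
25 % on a 6,000-row fixture) is verified in the test suite.

**Prediction.**  Inverse-logit of the linear predictor with the new-study
random effect set to 0 (the population-median study); a fitted study's own
effect can be supplied.  Probability surfaces evaluate cells at
representative values: biomarker-bin and band midpoints, open-ended bands
at the lower edge plus half the preceding band's width (BMI ≥ 30 at 32.5).
Coefficients serialize to JSON and reload for prediction without
refitting.

## Cross-validation and metrics

Per round, studies are randomly partitioned into 10 folds with sizes
differing by at most one; each fold's studies are held out once, the model
is refitted on the rest, and held-out rows are predicted with random
effect 0 (the held-out study is unseen).  Metrics are computed on the
pooled held-out predictions of each round and summarized over rounds
(default 20) as mean and range.  The C-statistic uses the rank-sum
(Mann–Whitney) identity with ties counted ½; an exhaustive pair
enumeration in the tests confirms exact agreement.  Prevalence errors
compare mean predicted probability with observed prevalence within
study × sex × age-group (18–39 / 40–59 / 60+) strata, in percentage
points; strata under 10 participants are dropped with a warning and strata
are averaged unweighted (each cell counts once), with participant-weighted
averaging available.  All fold draws derive from one seed.

## Problem sizes in the shipped checks

The packaged checks run at desk scale, chosen so every assertion has
comfortable statistical headroom: classification oracles at n = 10,000;
LOF oracle at n = 2,000; log-binomial recovery at 30 studies × ~1,667 rows
(n ≈ 50,000) with the reduced MCMC preset, plus 20 null-effect replicates
at 30 × 200 for credible-interval coverage; prediction-equation recovery
at 40 studies × 1,000 rows over 4 regions; cross-validation at 50 studies
× 1,000 rows with 20 rounds of 10 folds.  Because single-replicate
estimates of study-level contrasts (region, method) at 40 studies have a
sampling error comparable to the 0.05 log-odds tolerance, the recovery
check asserts per-replicate tolerance for individual-level coefficients
and replicate-averaged (6 replicates) tolerance for all fixed effects —
the averaged check is a bias test with ~2.8σ headroom rather than a coin
flip on noise.

## Numerical choices and degenerate inputs

- Exclusion reasons are first-triggered; the cascade order is fixed and
  logged.  Range-filter intervals are closed; values exactly on a bound
  are retained.  LOF ties at exactly 2 are retained.
- LOF with n < 2 is a warned no-op; k is clipped to n − 1.
- Age-standardization with weights equal to the sample's own age
  distribution reproduces crude prevalence to 1e-12 (identity check).
- The MCMC initial state places the intercept at the log event rate so the
  p ≤ 1 constraint is satisfied from the first iteration.
- σ_u² Gibbs sampling inverts the truncated inverse-gamma CDF; when the
  prior interval carries essentially no mass the nearer bound is taken.
- The mixed-logistic Newton step uses step-halving on the penalized
  objective; weights are floored at 1e-10; the variance is floored at
  1e-8 (effectively a fixed-effects fit when the data demand σ² → 0).
- C-statistic is undefined (raises) without both outcome classes; folds
  whose training outcome is constant are skipped with a warning.

## Known limitations

- The synthetic composition of screen-detected diabetes is more
  HbA1c-weighted than pooled real-world data: marginal exceedance rates
  follow directly from the plausibility log-scale means/sds, which were
  fixed from regional summary characteristics rather than tuned to match
  composition shares.
- The mixed-logistic fitter is an approximate-ML (penalized
  quasi-likelihood/Laplace) estimator; its small-σ bias is negligible at
  the variances used here (σ ≈ 0.3) but would grow for large random-effect
  variances or tiny cluster sizes.
- The three log-binomial outcome models are fitted independently, so
  fitted category probabilities need not sum to 1 across outcomes.
- Sensitivity re-runs (dropping named studies or all capillary studies)
  are generic configuration filters; no special-case handling of
  single-study idiosyncrasies is attempted.
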