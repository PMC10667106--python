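# glyconcord

Concordance and discordance of **fasting plasma glucose (FPG)** and
**HbA1c** in detecting undiagnosed diabetes, as a tested, reusable pipeline
for pooled multi-study survey data.

Population surveys diagnose ("screen-detect") diabetes from a single blood
measurement: FPG ≥ 7.0 mmol/L and/or HbA1c ≥ 6.5 %.  The two biomarkers
capture different physiology — a fasting snapshot versus a 2–3 month
average — and frequently disagree, so surveillance based on only one of
them can misstate prevalence, with the direction and size of the error
varying by world region, sex, age and BMI.  This package implements the
full analysis chain for studying that discordance:

1. **Synthetic multi-study cohorts** (`glyconcord.synthetic`) with known
   ground truth: studies in seven world regions, region-specific joint
   (log FPG, log HbA1c) distributions, a calibrated diagnosis mechanism,
   study-level heterogeneity, and injected data artifacts.  Real
   individual-level survey databases of this kind are access-restricted;
   the generator makes every downstream stage testable against exact
   known quantities.
2. **Data cleaning** (`glyconcord.cleaning`): exclusion cascade (pregnancy,
   under-18, follow-up rounds, missing data), plausible-range filter,
   capillary→plasma glucose conversion (×1.11), and a **local outlier
   factor (LOF)** filter that removes implausible (FPG, HbA1c) pairs whose
   local density is less than half the average of their 100 nearest
   neighbours (LOF > 2), with a full exclusion audit log.
3. **Classification & prevalence** (`glyconcord.classify`): the five-way
   partition — diagnosed / isolated elevated FPG / isolated elevated
   HbA1c / both elevated / no diabetes — with crude and age-standardized
   prevalence (WHO world standard population) and the composition of
   screen-detected diabetes.
4. **Association models** (`glyconcord.assoc`): three Bayesian
   **log-binomial regressions** with study random effects,

   y_i ~ Bernoulli(p_i),  log p_i = x_i′β + u_{study(i)},  u_j ~ N(0, σ_u²),

   fitted by an adaptive Metropolis-within-Gibbs sampler that enforces
   p ≤ 1 exactly; exp(β) are **prevalence ratios (PRs)** reported with 95 %
   credible intervals and one-sided posterior probabilities.
5. **Prediction equations** (`glyconcord.predeq`): nine registered
   mixed-effects logistic models estimating P(HbA1c ≥ 6.5 % | FPG, sex,
   age, BMI, method, region) and the reverse direction, with study random
   intercepts, plus probability-surface tables over sex × age × region ×
   BMI × biomarker grids.
6. **Validation** (`glyconcord.validate`): 20 × 10-fold **study-holdout
   cross-validation** with the C-statistic (individual level) and mean /
   mean absolute prevalence error across study × sex × age-group strata
   (population level).
7. **Pipeline & CLI** (`glyconcord.pipeline`, `glyconcord` command): one
   YAML configuration, one master seed, byte-reproducible artifacts.

## Worked example

```python
from glyconcord import default_generator_config
from glyconcord.synthetic import generate_cohort
from glyconcord.cleaning import clean
from glyconcord.classify import (classify_frame, crude_prevalence,
    age_standardized_prevalence, composition_of_screen_detected)

cfg = default_generator_config(n_studies_per_region=3,
                               participants_per_study=(1000, 1800), seed=1)
participants, studies, truth = generate_cohort(cfg)
cleaned, log = clean(participants, studies)
categories = classify_frame(cleaned)
crude = crude_prevalence(cleaned, categories)
std = age_standardized_prevalence(cleaned, categories=categories)
```

Output of the accompanying summary prints:

```
generated 31843 participants in 21 studies; 1107 excluded
  ({'pregnant': 309, 'under_18': 235, 'followup_round': 0,
    'missing_diagnosis_info': 0, 'missing_biomarker': 465,
    'out_of_range': 1, 'implausible_pair': 97})
total diabetes: crude 18.6%, age-standardized 16.0%
screen-detected composition (crude): isolated fpg 27%, isolated hba1c 55%, both 17%
undiagnosed FPG-HbA1c correlation across regions: 0.45-0.75
```

Reading: of ~31.8k simulated adults, the cleaning cascade removed 1,107
rows and logged why (including 97 implausible biomarker pairs caught by
the LOF filter).  18.6 % of the cleaned sample has diabetes (diagnosed or
screen-detected); standardizing to the WHO age structure lowers this to
16.0 % because the sample is older than the standard.  Among the
screen-detected, only 17 % are elevated on **both** biomarkers — the rest
would be missed by one of the two tests — and the FPG–HbA1c correlation
among the undiagnosed spans the configured regional range.

The same run from a shell:

```bash
glyconcord run-all --seed 1 --out myrun/
```

writes the cleaned table, exclusion log, prevalence/composition tables, PR
summaries, prediction-model coefficient files, probability surfaces, a
cross-validation report and a manifest to `myrun/`.

## Documentation

`docs/methods.md` describes the generating model, the samplers and
fitters, all tunable parameters with units and defaults, numerical
choices, and known limitations.
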