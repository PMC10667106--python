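"""Seeded synthetic multi-study cohorts with known ground truth.

The generator draws, for each study, participant covariates (sex, age, BMI)
and a bivariate-normal pair (log FPG, log HbA1c) whose mean is shifted by a
shared covariate risk score and a study-level random effect, with the
region's configured correlation.  A logistic diagnosis mechanism, calibrated
by bisection per study, produces the configured diagnosed fraction among
participants in the diabetic range.  Data artifacts (pregnancy, under-18
records, missing biomarkers, implausible discordant biomarker pairs) are
injected at configured rates so the cleaning cascade has true positives to
find.

Every quantity needed to score downstream methods is recorded in a
:class:`GroundTruth` object: the study random effects and, per participant,
the exact marginal and conditional probabilities of each biomarker exceeding
its diagnostic threshold.

Two further simulators draw data directly from the regression structures
used downstream (a log-link binomial model with study random effects, and a
mixed-effects logistic prediction model), with user-specified true
coefficients, for parameter-recovery and cross-validation checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, truncnorm

from .config import GeneratorConfig, ConfigError
from .constants import FPG_THRESHOLD, HBA1C_THRESHOLD, PARTICIPANT_COLUMNS, STUDY_COLUMNS
from .regions import Region, DEFAULT_POPULATED_REGIONS

_REGION_CODE = {
    Region.CENTRAL_EASTERN_EUROPE: "cee",
    Region.CENTRAL_ASIA_MIDDLE_EAST_NORTH_AFRICA: "camena",
    Region.HIGH_INCOME_WESTERN: "hiw",
    Region.LATIN_AMERICA_CARIBBEAN: "lac",
    Region.SOUTH_ASIA: "sa",
    Region.EAST_SOUTHEAST_ASIA_PACIFIC: "eseap",
    Region.SUB_SAHARAN_AFRICA: "ssa",
    Region.OCEANIA: "oce",
}

ARTIFACT_NONE = ""
ARTIFACT_TYPES = ("pregnancy", "under18", "missing_biomarker", "implausible_pair")


@dataclass
class GroundTruth:
    """Oracle record of the generating process.

    ``table`` is indexed by participant id and stores, per participant, the
    artifact label (empty for clean rows), the latent log-scale means, the
    region dispersion/correlation, and the exact threshold-exceedance
    probabilities: marginal ``p_fpg_exceeds``/``p_hba1c_exceeds`` and
    conditional ``p_hba1c_given_fpg``/``p_fpg_given_hba1c`` given the
    realized value of the other biomarker.
    """

    covariate_effects: object
    study_effects: dict[str, float]
    table: pd.DataFrame

    def true_probability(self, participant_id: str, direction: str) -> float:
        """Exact generator probability that the target biomarker exceeds its
        threshold given the conditioning biomarker and covariates.

        ``direction`` is ``"fpg_to_hba1c"`` (probability HbA1c >= 6.5% given
        FPG) or ``"hba1c_to_fpg"``.
        """
        if participant_id not in self.table.index:
            raise KeyError(f"participant {participant_id!r} not in ground truth")
        row = self.table.loc[participant_id]
        if direction == "fpg_to_hba1c":
            return float(row["p_hba1c_given_fpg"])
        if direction == "hba1c_to_fpg":
            return float(row["p_fpg_given_hba1c"])
        raise ValueError(f"unknown direction {direction!r}")

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            covariate_effects=self.covariate_effects,
            study_effects={**self.study_effects, **other.study_effects},
            table=pd.concat([self.table, other.table]),
        )


def _study_seed(root: int, index: int) -> int:
    """Deterministic per-study seed derived from the config seed."""
    ss = np.random.SeedSequence([root, index])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def generate_studies(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the study-level metadata table.

    One row per study: region, mid-year (>= 2000), measurement-method flags
    drawn from the region's portable/capillary fractions, plus the study's
    random-effect value and a derived per-study seed so that participant
    generation is reproducible study by study.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    regions = [
        r for r in DEFAULT_POPULATED_REGIONS if r.value in config.region_params
    ]
    # Preserve the configured region order, not enum order, for extra regions.
    extra = [
        Region(k) for k in config.region_params if Region(k) not in regions
    ]
    regions = regions + extra

    rows = []
    idx = 0
    y0, y1 = config.mid_year_range
    for region in regions:
        params = config.params_for(region)
        for k in range(config.n_studies_per_region):
            idx += 1
            study_id = f"{_REGION_CODE[region]}{k + 1:02d}"
            capillary = rng.random() < params.capillary_fraction
            rows.append(
                {
                    "study_id": study_id,
                    "region": region.value,
                    "mid_year": int(rng.integers(y0, y1 + 1)),
                    "fpg_portable": bool(rng.random() < params.portable_device_fraction),
                    "hba1c_portable": bool(rng.random() < params.portable_device_fraction),
                    "fpg_capillary": capillary,
                    # Among capillary studies, some devices already report
                    # plasma-equivalent values and need no conversion.
                    "capillary_plasma_equivalent": bool(capillary and rng.random() < 0.4),
                    "random_effect": float(rng.normal(0.0, config.study_re_sd)),
                    "study_seed": _study_seed(config.seed, idx),
                }
            )
    return pd.DataFrame(rows, columns=STUDY_COLUMNS + ["random_effect", "study_seed"])


def _draw_log_biomarkers(rng, params, rho: float, mean_lf, mean_lh, n: int):
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    lf = mean_lf + params.fpg_log_sd * z1
    lh = mean_lh + params.hba1c_log_sd * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)
    return lf, lh


def _calibrate_diagnosis_intercept(z: np.ndarray, slope: float, target: float) -> float:
    """Bisection for the intercept a such that mean(expit(a + slope*z)) = target."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(np.mean(expit(mid + slope * z))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


_DIAGNOSIS_SLOPE = 2.0

_RHO_CAL_CACHE: dict[tuple, float] = {}


def _latent_correlation(config: GeneratorConfig, region: Region) -> float:
    """Latent bivariate-normal correlation calibrated so the observable
    raw-scale correlation among the undiagnosed matches the configured
    value.

    The configured ``biomarker_correlation`` is the correlation reported in
    survey analyses: Pearson r of (FPG, HbA1c) among participants without a
    previous diagnosis.  Removing the diagnosed truncates the joint upper
    tail and attenuates that correlation relative to the generating noise
    correlation, so the latter is solved for by bisection on a fixed,
    internally seeded Monte-Carlo sample (deterministic; cached per region
    parameterization).
    """
    params = config.params_for(region)
    eff = config.covariate_effects
    key = (
        region.value,
        params.fpg_log_mean,
        params.fpg_log_sd,
        params.hba1c_log_mean,
        params.hba1c_log_sd,
        params.biomarker_correlation,
        params.diagnosed_fraction_target,
        params.bmi_mean,
        params.bmi_sd,
        eff.sex_male,
        eff.age_per_decade,
        eff.bmi_per_5units,
        eff.fpg_slope(region),
        config.age_mean,
        config.age_sd,
        config.female_fraction,
        config.study_re_sd,
    )
    if key in _RHO_CAL_CACHE:
        return _RHO_CAL_CACHE[key]

    target = params.biomarker_correlation
    n_cal = 60_000
    rng = np.random.default_rng(1_234_567)
    sex_male = rng.random(n_cal) >= config.female_fraction
    a = (18.0 - config.age_mean) / config.age_sd
    b = (95.0 - config.age_mean) / config.age_sd
    age = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd, size=n_cal, random_state=rng)
    bmi = np.clip(rng.normal(params.bmi_mean, params.bmi_sd, size=n_cal), 15.0, 60.0)
    risk = (
        eff.sex_male * sex_male
        + eff.age_per_decade * (age - 50.0) / 10.0
        + eff.bmi_per_5units * (bmi - 27.0) / 5.0
    )
    # u = 0: the calibration target is the within-study correlation (a
    # study's shared random effect adds no within-study variance).
    mean_lf = params.fpg_log_mean + eff.fpg_slope(region) * risk
    mean_lh = params.hba1c_log_mean + risk
    z1 = rng.standard_normal(n_cal)
    z2 = rng.standard_normal(n_cal)
    diag_draw = rng.random(n_cal)

    def undiagnosed_corr(rho: float) -> float:
        lf = mean_lf + params.fpg_log_sd * z1
        lh = mean_lh + params.hba1c_log_sd * (rho * z1 + np.sqrt(1 - rho**2) * z2)
        fpg, hba1c = np.exp(lf), np.exp(lh)
        zlat = 0.5 * (
            (lf - params.fpg_log_mean) / params.fpg_log_sd
            + (lh - params.hba1c_log_mean) / params.hba1c_log_sd
        )
        diabetic = (fpg >= FPG_THRESHOLD) | (hba1c >= HBA1C_THRESHOLD)
        undiag = np.ones(n_cal, dtype=bool)
        if diabetic.any() and params.diagnosed_fraction_target > 0:
            a0 = _calibrate_diagnosis_intercept(
                zlat[diabetic], _DIAGNOSIS_SLOPE, params.diagnosed_fraction_target
            )
            p_diag = expit(a0 + _DIAGNOSIS_SLOPE * zlat[diabetic])
            undiag[diabetic] = diag_draw[diabetic] >= p_diag
        f, h = fpg[undiag], hba1c[undiag]
        return float(np.corrcoef(f, h)[0, 1])

    lo = max(-0.99, target - 0.02)
    hi = min(0.995, target + 0.20)
    if undiagnosed_corr(hi) < target:
        rho_lat = hi
    else:
        for _ in range(18):
            mid = 0.5 * (lo + hi)
            if undiagnosed_corr(mid) < target:
                lo = mid
            else:
                hi = mid
        rho_lat = 0.5 * (lo + hi)
    _RHO_CAL_CACHE[key] = rho_lat
    return rho_lat


def generate_participants(
    study: pd.Series | dict, config: GeneratorConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one study's participant table plus its ground truth."""
    config.validate()
    study = dict(study)
    region = Region(study["region"])
    params = config.params_for(region)
    eff = config.covariate_effects
    rng = np.random.default_rng(study["study_seed"])

    n = int(rng.integers(config.participants_per_study[0], config.participants_per_study[1] + 1))
    sex_male = rng.random(n) >= config.female_fraction
    a, b = (18.0 - config.age_mean) / config.age_sd, (95.0 - config.age_mean) / config.age_sd
    age = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng)
    bmi = np.clip(rng.normal(params.bmi_mean, params.bmi_sd, size=n), 15.0, 60.0)

    # Shared covariate risk score on the log-biomarker scale.
    risk = (
        eff.sex_male * sex_male
        + eff.age_per_decade * (age - 50.0) / 10.0
        + eff.bmi_per_5units * (bmi - 27.0) / 5.0
    )
    u = float(study["random_effect"])
    slope_f = eff.fpg_slope(region)
    mean_lf = params.fpg_log_mean + slope_f * risk + u
    mean_lh = params.hba1c_log_mean + risk + u

    # Latent noise correlation, calibrated so that after the diagnosed are
    # set aside the observable correlation matches the configured value.
    rho = _latent_correlation(config, region)
    sf, sh = params.fpg_log_sd, params.hba1c_log_sd
    lf, lh = _draw_log_biomarkers(rng, params, rho, mean_lf, mean_lh, n)
    fpg = np.exp(lf)
    hba1c = np.exp(lh)

    # Exact threshold-exceedance probabilities under the generating model.
    tf, th = np.log(FPG_THRESHOLD), np.log(HBA1C_THRESHOLD)
    p_f = norm.sf((tf - mean_lf) / sf)
    p_h = norm.sf((th - mean_lh) / sh)
    cond_sd_h = sh * np.sqrt(1.0 - rho**2)
    cond_mean_h = mean_lh + rho * sh / sf * (lf - mean_lf)
    p_h_given_f = norm.sf((th - cond_mean_h) / cond_sd_h)
    cond_sd_f = sf * np.sqrt(1.0 - rho**2)
    cond_mean_f = mean_lf + rho * sf / sh * (lh - mean_lh)
    p_f_given_h = norm.sf((tf - cond_mean_f) / cond_sd_f)

    # Diagnosis: logistic in latent glycemia among the diabetic-range rows,
    # intercept tuned by bisection to hit the region's diagnosed fraction.
    zlat = 0.5 * ((lf - params.fpg_log_mean) / sf + (lh - params.hba1c_log_mean) / sh)
    diabetic = (fpg >= FPG_THRESHOLD) | (hba1c >= HBA1C_THRESHOLD)
    diagnosed = np.zeros(n, dtype=bool)
    if diabetic.any() and params.diagnosed_fraction_target > 0:
        a0 = _calibrate_diagnosis_intercept(
            zlat[diabetic], _DIAGNOSIS_SLOPE, params.diagnosed_fraction_target
        )
        p_diag = expit(a0 + _DIAGNOSIS_SLOPE * zlat[diabetic])
        diagnosed[diabetic] = rng.random(diabetic.sum()) < p_diag
    on_med = diagnosed & (rng.random(n) < 0.8)

    sex = np.where(sex_male, "male", "female")
    pregnant = np.zeros(n, dtype=bool)

    # Artifact injection: one categorical draw per row keeps artifact types
    # disjoint; artifact rows are flagged in the ground truth so structural
    # checks can be restricted to clean rows.
    ar = config.artifact_rates
    cut = np.cumsum([ar.pregnancy, ar.under18, ar.missing_biomarker, ar.implausible_pair])
    draw = rng.random(n)
    artifact = np.full(n, ARTIFACT_NONE, dtype=object)
    artifact[draw < cut[0]] = "pregnancy"
    artifact[(draw >= cut[0]) & (draw < cut[1])] = "under18"
    artifact[(draw >= cut[1]) & (draw < cut[2])] = "missing_biomarker"
    artifact[(draw >= cut[2]) & (draw < cut[3])] = "implausible_pair"

    m = artifact == "pregnancy"
    sex[m] = "female"
    pregnant[m] = True

    m = artifact == "under18"
    age[m] = rng.uniform(12.0, 17.99, size=int(m.sum()))

    m = artifact == "missing_biomarker"
    if m.any():
        which = rng.random(int(m.sum())) < 0.5
        idx = np.flatnonzero(m)
        fpg[idx[which]] = np.nan
        hba1c[idx[~which]] = np.nan

    # Implausible pairs: extreme discordance far outside the generating
    # correlation structure (one biomarker near the 99.9th percentile of its
    # region, the other near the 5th), e.g. FPG 28 mmol/L with HbA1c 5%.
    m = artifact == "implausible_pair"
    if m.any():
        idx = np.flatnonzero(m)
        hi_f = rng.random(idx.size) < 0.5
        fpg[idx[hi_f]] = np.exp(params.fpg_log_mean + 3.2 * sf)
        hba1c[idx[hi_f]] = np.exp(params.hba1c_log_mean - 1.7 * sh)
        fpg[idx[~hi_f]] = np.exp(params.fpg_log_mean - 1.7 * sf)
        hba1c[idx[~hi_f]] = np.exp(params.hba1c_log_mean + 3.2 * sh)

    pid = np.array([f"{study['study_id']}-{i:05d}" for i in range(n)])
    participants = pd.DataFrame(
        {
            "participant_id": pid,
            "study_id": study["study_id"],
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "fpg": fpg,
            "hba1c": hba1c,
            "diagnosed_previously": diagnosed,
            "on_glucose_lowering_medication": on_med,
            "pregnant": pregnant,
            "visit_index": 1,
        },
        columns=PARTICIPANT_COLUMNS,
    )
    truth_table = pd.DataFrame(
        {
            "artifact": artifact,
            "mean_log_fpg": mean_lf,
            "mean_log_hba1c": mean_lh,
            "fpg_log_sd": sf,
            "hba1c_log_sd": sh,
            "correlation": rho,
            "target_correlation": params.biomarker_correlation,
            "p_fpg_exceeds": p_f,
            "p_hba1c_exceeds": p_h,
            "p_hba1c_given_fpg": p_h_given_f,
            "p_fpg_given_hba1c": p_f_given_h,
        },
        index=pd.Index(pid, name="participant_id"),
    )
    truth = GroundTruth(
        covariate_effects=eff,
        study_effects={str(study["study_id"]): u},
        table=truth_table,
    )
    return participants, truth


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the full multi-study cohort: (participants, studies, truth)."""
    studies = generate_studies(config)
    frames, truths = [], []
    for _, study in studies.iterrows():
        p, t = generate_participants(study, config)
        frames.append(p)
        truths.append(t)
    participants = pd.concat(frames, ignore_index=True)
    truth = truths[0]
    for t in truths[1:]:
        truth = truth.merge(t)
    return participants, studies, truth


# ---------------------------------------------------------------------------
# Direct simulators from the downstream regression structures
# ---------------------------------------------------------------------------


def simulate_log_binomial(
    true_log_pr: dict[str, float],
    n_studies: int = 30,
    rows_per_study: int = 1000,
    re_sd: float = 0.10,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, dict[str, float]]:
    """Simulate outcomes from a log-link binomial model with study random
    effects, for parameter-recovery checks of the association stage.

    ``true_log_pr`` maps covariate names to true log prevalence ratios and
    must include ``"intercept"``; recognized covariates are ``male`` (0/1),
    ``age10`` (age in decades) and ``bmi5`` (BMI per 5 kg/m^2).  Returns
    (design frame with a ``study`` column, outcome array, the truth dict).
    The intercept is chosen low enough that all event probabilities are
    below 1; any rare excursion is truncated just below 1.
    """
    rng = np.random.default_rng(seed)
    n = n_studies * rows_per_study
    study = np.repeat([f"s{j:03d}" for j in range(n_studies)], rows_per_study)
    u = rng.normal(0.0, re_sd, size=n_studies)
    male = (rng.random(n) < 0.5).astype(float)
    age10 = np.clip(rng.normal(5.5, 1.4, size=n), 1.8, 9.5)
    bmi5 = np.clip(rng.normal(5.6, 1.0, size=n), 3.0, 12.0)
    eta = np.full(n, true_log_pr["intercept"])
    eta += true_log_pr.get("male", 0.0) * male
    eta += true_log_pr.get("age10", 0.0) * age10
    eta += true_log_pr.get("bmi5", 0.0) * bmi5
    eta += u[np.repeat(np.arange(n_studies), rows_per_study)]
    p = np.minimum(np.exp(eta), 1.0 - 1e-9)
    y = (rng.random(n) < p).astype(int)
    design = pd.DataFrame(
        {"male": male, "age10": age10, "bmi5": bmi5, "study": study}
    )
    return design, y, dict(true_log_pr)


def simulate_prediction_cohort(
    spec,
    coefficients: dict[str, float],
    n_studies: int = 40,
    rows_per_study: int = 1000,
    re_variance: float = 0.09,
    regions: tuple[str, ...] | None = None,
    seed: int = 0,
    orthogonalize_re: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Simulate a cohort directly from a prediction-equation structure.

    ``spec`` is a :class:`glyconcord.predeq.PredictionModelSpec`; the outcome
    is drawn from a logistic model with the supplied true ``coefficients``
    (keys must match the spec's design column names) plus a study random
    intercept with variance ``re_variance``.  Returns (participants frame,
    studies frame, true per-row probability with the random effect included,
    study random-effect values).  The participant frame carries the realized
    outcome in an ``outcome`` column and has no previously diagnosed rows,
    matching the training population of the prediction equations.

    With ``orthogonalize_re`` (default) the drawn random effects are
    residualized against the study-level design (region and method columns)
    and rescaled to mean square ``re_variance``.  Region and method are
    study-level covariates, so with a finite number of studies the realized
    mean random effect of, say, one region's studies is statistically
    inseparable from that region's fixed effect; orthogonalizing removes
    this design confounding so that recovery checks measure estimator error
    rather than an information-theoretic floor.  Disable it to simulate
    fully unconstrained random effects.
    """
    from .predeq import design_matrix

    rng = np.random.default_rng(seed)
    if regions is None:
        regions = tuple(r.value for r in DEFAULT_POPULATED_REGIONS)
    n = n_studies * rows_per_study
    study_ids = [f"p{j:03d}" for j in range(n_studies)]
    study_region = [regions[j % len(regions)] for j in range(n_studies)]
    # Method flags drawn independently of region so that study-level design
    # columns are not collinear by construction.
    studies = pd.DataFrame(
        {
            "study_id": study_ids,
            "region": study_region,
            "mid_year": 2012,
            "fpg_portable": rng.random(n_studies) < 0.15,
            "hba1c_portable": rng.random(n_studies) < 0.15,
            "fpg_capillary": False,
            "capillary_plasma_equivalent": False,
        },
        columns=STUDY_COLUMNS,
    )
    g = np.repeat(np.arange(n_studies), rows_per_study)
    if spec.direction == "fpg_to_hba1c":
        biomarker = np.clip(rng.normal(5.6, 1.1, size=n), 2.6, 14.0)
        fpg, hba1c = biomarker, np.full(n, np.nan)
    else:
        biomarker = np.clip(rng.normal(5.6, 0.9, size=n), 3.2, 14.0)
        fpg, hba1c = np.full(n, np.nan), biomarker
    participants = pd.DataFrame(
        {
            "participant_id": [f"{study_ids[j]}-{i:05d}" for i, j in enumerate(g)],
            "study_id": np.array(study_ids, dtype=object)[g],
            "sex": np.where(rng.random(n) < 0.5, "male", "female"),
            "age": np.clip(rng.normal(50, 16, size=n), 18, 95),
            "bmi": np.clip(rng.normal(27, 5, size=n), 15, 55),
            "fpg": fpg,
            "hba1c": hba1c,
            "diagnosed_previously": False,
            "on_glucose_lowering_medication": False,
            "pregnant": False,
            "visit_index": 1,
        },
        columns=PARTICIPANT_COLUMNS,
    )
    X, names = design_matrix(spec, participants, studies)
    missing = [c for c in names if c not in coefficients]
    if missing:
        raise ConfigError(f"coefficients missing for design columns: {missing}")
    beta = np.array([coefficients[c] for c in names])
    u = rng.normal(0.0, np.sqrt(re_variance), size=n_studies)
    if orthogonalize_re and re_variance > 0:
        S = np.column_stack(
            [
                np.ones(n_studies),
                *(
                    (np.array(study_region) == r).astype(float)
                    for r in sorted(set(study_region))
                ),
                studies["fpg_portable"].to_numpy(dtype=float),
                studies["hba1c_portable"].to_numpy(dtype=float),
            ]
        )
        u = u - S @ np.linalg.lstsq(S, u, rcond=None)[0]
        u *= np.sqrt(re_variance / np.mean(u**2))
    eta = X @ beta + u[g]
    p = expit(eta)
    participants["outcome"] = (rng.random(n) < p).astype(int)
    return participants, studies, p, u
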