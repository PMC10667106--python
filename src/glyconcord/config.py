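"""Configuration objects for the synthetic multi-study cohort generator.

The generator emulates the statistical structure of a pooled database of
population-based glycemia surveys: several studies per world region, a
region-specific joint distribution of fasting plasma glucose (FPG, mmol/L)
and HbA1c (%, NGSP), a diagnosis mechanism producing region-varying
diagnosed fractions, age/sex/BMI covariate structure, study-level
heterogeneity, measurement-method flags, and injected data artifacts
(pregnancy, under-18 records, missing biomarkers, implausible biomarker
pairs) for the cleaning stage to find.

All defaults are plausibility values chosen to echo the published summary
characteristics of such databases (for example south Asia with lower BMI
and a higher undiagnosed share, FPG-HbA1c correlations spanning roughly
0.51-0.76 across regions); they are not estimates of any real study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

from .regions import Region, DEFAULT_POPULATED_REGIONS


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


@dataclass
class RegionParams:
    """Generating parameters for one world region.

    ``fpg_log_mean``/``hba1c_log_mean`` and the corresponding log-scale
    standard deviations parameterize a bivariate normal for
    (log FPG, log HbA1c); both biomarkers are strictly positive and
    right-skewed, so the log scale keeps the correlation interpretable.
    """

    fpg_log_mean: float
    fpg_log_sd: float
    hba1c_log_mean: float
    hba1c_log_sd: float
    biomarker_correlation: float
    diagnosed_fraction_target: float
    bmi_mean: float
    bmi_sd: float
    portable_device_fraction: float = 0.10
    capillary_fraction: float = 0.06

    def validate(self, region: str) -> None:
        for name in ("fpg_log_sd", "hba1c_log_sd", "bmi_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"region_params[{region}].{name} must be > 0")
        if not -1.0 < self.biomarker_correlation < 1.0:
            raise ConfigError(
                f"region_params[{region}].biomarker_correlation must be in (-1, 1)"
            )
        for name in (
            "diagnosed_fraction_target",
            "portable_device_fraction",
            "capillary_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"region_params[{region}].{name} must be in [0, 1]")


@dataclass
class CovariateEffects:
    """Ground-truth covariate effects on the log-biomarker means.

    ``sex_male``, ``age_per_decade`` and ``bmi_per_5units`` shift the latent
    mean of both log biomarkers (a shared glycemia risk score);
    ``region_fpg_slopes`` optionally rescales how strongly that score moves
    log FPG in a given region (1.0 everywhere by default).
    """

    sex_male: float = 0.010
    age_per_decade: float = 0.022
    bmi_per_5units: float = 0.040
    region_fpg_slopes: dict[str, float] = field(default_factory=dict)

    def fpg_slope(self, region: Region) -> float:
        return self.region_fpg_slopes.get(region.value, 1.0)


@dataclass
class ArtifactRates:
    """Per-participant probabilities of each injected data artifact."""

    pregnancy: float = 0.010
    under18: float = 0.008
    missing_biomarker: float = 0.015
    implausible_pair: float = 0.002

    def validate(self) -> None:
        total = 0.0
        for name in ("pregnancy", "under18", "missing_biomarker", "implausible_pair"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"artifact_rates.{name} must be in [0, 1]")
            total += v
        if total > 1.0:
            raise ConfigError("artifact_rates must sum to at most 1")


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic multi-study cohort."""

    n_studies_per_region: int
    participants_per_study: tuple[int, int]
    region_params: dict[str, RegionParams]
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    study_re_sd: float = 0.05
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    seed: int = 0
    # Age structure (years) of sampled adults before artifact injection.
    age_mean: float = 50.0
    age_sd: float = 16.0
    female_fraction: float = 0.55
    mid_year_range: tuple[int, int] = (2000, 2021)

    def validate(self) -> None:
        if self.n_studies_per_region < 1:
            raise ConfigError("n_studies_per_region must be >= 1")
        lo, hi = self.participants_per_study
        if lo < 1 or hi < lo:
            raise ConfigError(
                "participants_per_study must be a (low, high) range with 1 <= low <= high"
            )
        if not self.region_params:
            raise ConfigError("region_params must not be empty")
        valid = {r.value for r in Region}
        for region, params in self.region_params.items():
            if region not in valid:
                raise ConfigError(f"region_params key {region!r} is not a known region")
            params.validate(region)
        if self.study_re_sd < 0:
            raise ConfigError("study_re_sd must be >= 0")
        self.artifact_rates.validate()
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction must be in [0, 1]")
        if self.age_sd <= 0:
            raise ConfigError("age_sd must be > 0")
        y0, y1 = self.mid_year_range
        if y0 < 2000 or y1 < y0:
            raise ConfigError("mid_year_range must satisfy 2000 <= low <= high")

    def params_for(self, region: Region) -> RegionParams:
        try:
            return self.region_params[region.value]
        except KeyError:
            raise ConfigError(f"region_params missing entry for {region.value}") from None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        d["region_params"] = {
            k: RegionParams(**v) for k, v in d.get("region_params", {}).items()
        }
        if "covariate_effects" in d:
            d["covariate_effects"] = CovariateEffects(**d["covariate_effects"])
        if "artifact_rates" in d:
            d["artifact_rates"] = ArtifactRates(**d["artifact_rates"])
        for key in ("participants_per_study", "mid_year_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


#: Region-level plausibility defaults: (fpg mmol/L geometric mean,
#: hba1c % geometric mean, correlation, diagnosed fraction, BMI mean).
_DEFAULT_REGION_TABLE: dict[Region, tuple[float, float, float, float, float]] = {
    Region.CENTRAL_EASTERN_EUROPE: (5.4, 5.4, 0.51, 0.68, 28.2),
    Region.CENTRAL_ASIA_MIDDLE_EAST_NORTH_AFRICA: (5.3, 5.6, 0.60, 0.67, 27.7),
    Region.HIGH_INCOME_WESTERN: (5.4, 5.3, 0.55, 0.70, 27.8),
    Region.LATIN_AMERICA_CARIBBEAN: (5.3, 5.4, 0.65, 0.55, 28.3),
    Region.SOUTH_ASIA: (5.6, 5.7, 0.70, 0.34, 23.1),
    Region.EAST_SOUTHEAST_ASIA_PACIFIC: (5.4, 5.6, 0.66, 0.50, 24.0),
    Region.SUB_SAHARAN_AFRICA: (5.6, 5.8, 0.76, 0.54, 26.3),
}


def default_region_params() -> dict[str, RegionParams]:
    import math

    out: dict[str, RegionParams] = {}
    for region, (fpg, hba1c, rho, diag, bmi) in _DEFAULT_REGION_TABLE.items():
        out[region.value] = RegionParams(
            fpg_log_mean=math.log(fpg),
            fpg_log_sd=0.18,
            hba1c_log_mean=math.log(hba1c),
            hba1c_log_sd=0.13,
            biomarker_correlation=rho,
            diagnosed_fraction_target=diag,
            bmi_mean=bmi,
            bmi_sd=5.0,
        )
    return out


def default_generator_config(
    n_studies_per_region: int = 3,
    participants_per_study: tuple[int, int] = (800, 1500),
    seed: int = 0,
) -> GeneratorConfig:
    """The packaged default configuration: 7 populated regions, Oceania empty."""
    cfg = GeneratorConfig(
        n_studies_per_region=n_studies_per_region,
        participants_per_study=participants_per_study,
        region_params=default_region_params(),
        seed=seed,
    )
    cfg.validate()
    return cfg


assert set(_DEFAULT_REGION_TABLE) == set(DEFAULT_POPULATED_REGIONS)
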