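"""Shared fixtures: small seeded synthetic cohorts built at test time."""

import math

import pandas as pd
import pytest

from glyconcord.config import (
    ArtifactRates,
    GeneratorConfig,
    RegionParams,
    default_generator_config,
)
from glyconcord.synthetic import generate_cohort


def single_region_config(
    rho: float = 0.76,
    n: int = 20_000,
    diagnosed: float = 0.54,
    artifacts: bool = False,
    seed: int = 0,
    study_re_sd: float = 0.0,
    region: str = "sub_saharan_africa",
) -> GeneratorConfig:
    """One-region, one-study configuration for focused distribution checks."""
    rates = ArtifactRates() if artifacts else ArtifactRates(0.0, 0.0, 0.0, 0.0)
    return GeneratorConfig(
        n_studies_per_region=1,
        participants_per_study=(n, n),
        region_params={
            region: RegionParams(
                fpg_log_mean=math.log(5.6),
                fpg_log_sd=0.18,
                hba1c_log_mean=math.log(5.8),
                hba1c_log_sd=0.13,
                biomarker_correlation=rho,
                diagnosed_fraction_target=diagnosed,
                bmi_mean=26.3,
                bmi_sd=5.0,
            )
        },
        artifact_rates=rates,
        study_re_sd=study_re_sd,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort() -> tuple[pd.DataFrame, pd.DataFrame, object]:
    """Default 7-region cohort, 2 studies per region, modest size."""
    cfg = default_generator_config(
        n_studies_per_region=2, participants_per_study=(600, 900), seed=42
    )
    return generate_cohort(cfg)
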