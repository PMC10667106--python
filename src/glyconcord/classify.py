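"""Diabetes-status classification and prevalence summaries.

Participants are partitioned into five mutually exclusive categories:
previously diagnosed diabetes (self-report or glucose-lowering medication,
regardless of biomarker levels); among the undiagnosed, screen-detected
diabetes manifested as isolated elevated FPG (FPG >= 7.0 mmol/L and
HbA1c < 6.5%), isolated elevated HbA1c, or elevated levels of both; and no
diabetes.  Prevalence is reported crude (all participants regardless of
age) and age-standardized as the weighted mean of age-band-specific values
using the WHO world standard population.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from enum import Enum
from importlib import resources

import numpy as np
import pandas as pd

from .constants import FPG_THRESHOLD, HBA1C_THRESHOLD


class GlycemicCategory(str, Enum):
    DIAGNOSED = "diagnosed"
    ISOLATED_ELEVATED_FPG = "isolated_elevated_fpg"
    ISOLATED_ELEVATED_HBA1C = "isolated_elevated_hba1c"
    BOTH_ELEVATED = "both_elevated"
    NO_DIABETES = "no_diabetes"


SCREEN_DETECTED = (
    GlycemicCategory.ISOLATED_ELEVATED_FPG,
    GlycemicCategory.ISOLATED_ELEVATED_HBA1C,
    GlycemicCategory.BOTH_ELEVATED,
)

CATEGORY_ORDER = [c.value for c in GlycemicCategory]


class ClassificationError(ValueError):
    pass


@dataclass
class StandardPopulation:
    """Contiguous age bands covering adults, with weights summing to 1."""

    lower_bounds: np.ndarray  # ascending band lower edges, years
    upper_bounds: np.ndarray  # matching upper edges; last may be inf
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("standard-population weights must be >= 0")
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError("standard-population weights must sum to 1")
        if np.any(self.lower_bounds[1:] != self.upper_bounds[:-1]):
            raise ValueError("age bands must be contiguous and non-overlapping")

    def band_index(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        idx = np.searchsorted(self.lower_bounds, ages, side="right") - 1
        bad = (idx < 0) | (ages >= self.upper_bounds[np.clip(idx, 0, len(self.weights) - 1)])
        if bad.any():
            raise ValueError(
                f"ages outside band coverage at rows {np.flatnonzero(bad)[:10].tolist()}"
            )
        return idx

    @property
    def n_bands(self) -> int:
        return len(self.weights)


#: Age-band edges used for standardization: 18-19, then 10-year bands, 80+.
DEFAULT_BAND_EDGES = [18, 20, 30, 40, 50, 60, 70, 80, float("inf")]


def who_standard_population(band_edges=None) -> StandardPopulation:
    """The WHO world standard population aggregated onto adult age bands.

    The packaged 5-year WHO standard table is aggregated onto the requested
    bands (default 18-19, 20-29, ..., 70-79, 80+), splitting 5-year source
    bands pro rata by years of overlap, and renormalized over 18+.
    """
    if band_edges is None:
        band_edges = DEFAULT_BAND_EDGES
    ref = resources.files("glyconcord.data") / "who_standard_population.json"
    table = json.loads(ref.read_text())["bands"]
    lo = np.asarray(band_edges[:-1], dtype=float)
    hi = np.asarray(band_edges[1:], dtype=float)
    weights = np.zeros(len(lo))
    for band in table:
        b_lo, b_hi, pct = band["lower"], band["upper"], band["percent"]
        overlap = np.maximum(
            0.0, np.minimum(hi, b_hi) - np.maximum(lo, b_lo)
        )
        weights += pct * overlap / (b_hi - b_lo)
    return StandardPopulation(lo, hi, weights / weights.sum())


def classify_participant(p) -> GlycemicCategory:
    """Classify one participant record (mapping or Series)."""
    if bool(p["diagnosed_previously"]) or bool(p["on_glucose_lowering_medication"]):
        return GlycemicCategory.DIAGNOSED
    fpg, hba1c = p["fpg"], p["hba1c"]
    if pd.isna(fpg) or pd.isna(hba1c):
        raise ClassificationError(
            "undiagnosed participant is missing a biomarker; subset to rows "
            "with both biomarkers before classification"
        )
    f, h = fpg >= FPG_THRESHOLD, hba1c >= HBA1C_THRESHOLD
    if f and h:
        return GlycemicCategory.BOTH_ELEVATED
    if f:
        return GlycemicCategory.ISOLATED_ELEVATED_FPG
    if h:
        return GlycemicCategory.ISOLATED_ELEVATED_HBA1C
    return GlycemicCategory.NO_DIABETES


def classify_frame(participants: pd.DataFrame) -> pd.Series:
    """Vectorized five-way classification; returns a category-name Series."""
    diagnosed = (
        participants["diagnosed_previously"].astype(bool)
        | participants["on_glucose_lowering_medication"].astype(bool)
    )
    fpg, hba1c = participants["fpg"], participants["hba1c"]
    missing = ~diagnosed & (fpg.isna() | hba1c.isna())
    if missing.any():
        raise ClassificationError(
            f"{int(missing.sum())} undiagnosed rows are missing a biomarker; "
            "subset to rows with both biomarkers before classification"
        )
    f = fpg >= FPG_THRESHOLD
    h = hba1c >= HBA1C_THRESHOLD
    out = np.select(
        [diagnosed, f & h, f, h],
        [
            GlycemicCategory.DIAGNOSED.value,
            GlycemicCategory.BOTH_ELEVATED.value,
            GlycemicCategory.ISOLATED_ELEVATED_FPG.value,
            GlycemicCategory.ISOLATED_ELEVATED_HBA1C.value,
        ],
        default=GlycemicCategory.NO_DIABETES.value,
    )
    return pd.Series(out, index=participants.index, name="category")


def _category_proportions(categories: pd.Series) -> pd.Series:
    counts = categories.value_counts().reindex(CATEGORY_ORDER, fill_value=0)
    return counts / counts.sum()


def crude_prevalence(participants: pd.DataFrame, categories: pd.Series | None = None) -> pd.Series:
    """Crude category proportions over all participants regardless of age."""
    if len(participants) == 0:
        raise ValueError("cannot compute prevalence of an empty table")
    if categories is None:
        categories = classify_frame(participants)
    return _category_proportions(categories)


def age_standardized_prevalence(
    participants: pd.DataFrame,
    std: StandardPopulation | None = None,
    categories: pd.Series | None = None,
) -> pd.Series:
    """Age-standardized category proportions: the weighted mean of the
    age-band-specific proportions under the standard population.

    Empty bands contribute by renormalizing the weights over populated
    bands (logged with a warning); proportions still sum to 1 exactly.
    """
    if len(participants) == 0:
        raise ValueError("cannot compute prevalence of an empty table")
    if std is None:
        std = who_standard_population()
    if categories is None:
        categories = classify_frame(participants)
    band = std.band_index(participants["age"].to_numpy())
    populated = np.unique(band)
    w = std.weights[populated]
    if len(populated) < std.n_bands:
        warnings.warn(
            f"{std.n_bands - len(populated)} empty age band(s); weights "
            "renormalized over populated bands"
        )
    w = w / w.sum()
    out = pd.Series(0.0, index=CATEGORY_ORDER)
    for weight, b in zip(w, populated):
        out = out + weight * _category_proportions(categories[band == b])
    return out


def composition_of_screen_detected(
    participants: pd.DataFrame,
    std: StandardPopulation | None = None,
    categories: pd.Series | None = None,
) -> pd.DataFrame:
    """Shares of the three screen-detected manifestations, scaled to 100%.

    Returns a frame with rows ``crude`` and ``age_standardized`` and one
    column per screen-detected category; each row sums to 1.
    """
    if categories is None:
        categories = classify_frame(participants)
    screen = [c.value for c in SCREEN_DETECTED]
    mask = categories.isin(screen)
    if not mask.any():
        raise ValueError("no screen-detected participants")
    crude = crude_prevalence(participants, categories)[screen]
    crude = crude / crude.sum()
    std_prev = age_standardized_prevalence(participants, std, categories)[screen]
    std_prev = std_prev / std_prev.sum()
    return pd.DataFrame([crude, std_prev], index=["crude", "age_standardized"])


def biomarker_correlation(
    participants: pd.DataFrame, method: str = "pearson"
) -> float:
    """Correlation between FPG and HbA1c among undiagnosed participants."""
    undiag = participants[
        ~(
            participants["diagnosed_previously"].astype(bool)
            | participants["on_glucose_lowering_medication"].astype(bool)
        )
    ]
    both = undiag[["fpg", "hba1c"]].dropna()
    if len(both) < 3:
        raise ValueError("need at least 3 undiagnosed rows with both biomarkers")
    return float(both["fpg"].corr(both["hba1c"], method=method))


def prevalence_table(
    participants: pd.DataFrame,
    studies: pd.DataFrame,
    std: StandardPopulation | None = None,
) -> pd.DataFrame:
    """Crude and age-standardized category proportions, per region and pooled.

    Long format: columns (scope, category, crude, age_standardized) where
    scope is a region name or ``all_studies``.
    """
    if std is None:
        std = who_standard_population()
    merged = participants.merge(studies[["study_id", "region"]], on="study_id")
    rows = []
    scopes = [("all_studies", merged)] + [
        (region, grp) for region, grp in merged.groupby("region")
    ]
    for scope, grp in scopes:
        categories = classify_frame(grp)
        crude = crude_prevalence(grp, categories)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stdz = age_standardized_prevalence(grp, std, categories)
        for cat in CATEGORY_ORDER:
            rows.append(
                {
                    "scope": scope,
                    "category": cat,
                    "crude": crude[cat],
                    "age_standardized": stdz[cat],
                }
            )
    return pd.DataFrame(rows)
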