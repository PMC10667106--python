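"""Exclusion cascade and biomarker-pair filtering.

The cleaning pipeline removes, in a fixed and logged order:

1. pregnant participants (glucose metabolism changes in pregnancy),
   participants under 18 years of age, follow-up measurement rounds (only a
   cohort's first round is analyzed) and rows missing required fields;
2. biomarker values outside configurable plausible ranges (treated as data
   recording errors);
3. after converting capillary whole-blood glucose to plasma-equivalent
   values, implausible (FPG, HbA1c) pairs detected with the local outlier
   factor (LOF): points whose local reachability density is less than half
   of the average density of their 100 nearest neighbors, i.e. LOF > 2.

Every excluded row is logged with its first-triggered reason, so stage
counts can be audited flowchart-style.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import LocalOutlierFactor

EXCLUSION_REASONS = (
    "pregnant",
    "under_18",
    "followup_round",
    "missing_diagnosis_info",
    "missing_biomarker",
    "out_of_range",
    "implausible_pair",
)

#: Conventional multiplicative factor from capillary whole-blood glucose to
#: plasma-equivalent glucose.
CAPILLARY_TO_PLASMA_FACTOR = 1.11


class CleaningConfigError(ValueError):
    pass


@dataclass
class RangeRule:
    """Closed plausible interval for one biomarker, in its own units."""

    biomarker: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise CleaningConfigError(
                f"RangeRule for {self.biomarker!r}: lower must be < upper"
            )


#: Default plausible ranges.  Chosen wide enough that extreme but possible
#: single values (FPG 28 mmol/L, HbA1c 17%) pass the range filter and are
#: left for the joint LOF filter to assess.
DEFAULT_RANGE_RULES = (
    RangeRule("fpg", 2.5, 30.0),
    RangeRule("hba1c", 3.0, 18.0),
)


@dataclass
class ExclusionLog:
    """Per-participant exclusion reasons and per-stage counts."""

    reasons: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    stage_counts: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_retained: int = 0

    def record(self, participant_ids, reason: str) -> None:
        if reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {reason!r}")
        new = pd.Series(reason, index=pd.Index(participant_ids), dtype=object)
        # first-triggered reason wins: never overwrite an existing entry
        new = new[~new.index.isin(self.reasons.index)]
        self.reasons = pd.concat([self.reasons, new])
        self.stage_counts[reason] = self.stage_counts.get(reason, 0) + len(new)

    @property
    def n_excluded(self) -> int:
        return int(len(self.reasons))

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_excluded": self.n_excluded,
            "stage_counts": dict(self.stage_counts),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def apply_exclusions(
    participants: pd.DataFrame,
    require_biomarkers: bool = True,
    require_bmi: bool = False,
    log: ExclusionLog | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Remove pregnant, under-18, follow-up-round and missing-data rows.

    Rows are retained in input order.  ``require_biomarkers`` controls
    whether rows missing FPG or HbA1c are excluded (the biomarker analysis
    set) or kept (the diagnosis-information set, which is larger because
    many surveys measure blood biomarkers only on a subsample).
    """
    if log is None:
        log = ExclusionLog(n_input=len(participants))
    p = participants
    keep = pd.Series(True, index=p.index)

    def _exclude(mask: pd.Series, reason: str) -> None:
        nonlocal keep
        hit = mask & keep
        log.record(p.loc[hit, "participant_id"], reason)
        keep &= ~hit

    _exclude(p["pregnant"].astype(bool), "pregnant")
    _exclude(p["age"] < 18.0, "under_18")
    _exclude(p["visit_index"] > 1, "followup_round")
    _exclude(p["diagnosed_previously"].isna(), "missing_diagnosis_info")
    if require_biomarkers:
        missing = p["fpg"].isna() | p["hba1c"].isna()
        if require_bmi:
            missing |= p["bmi"].isna()
        _exclude(missing, "missing_biomarker")
    retained = p[keep]
    log.n_retained = len(retained)
    return retained, log


def range_filter(
    participants: pd.DataFrame,
    rules=DEFAULT_RANGE_RULES,
    log: ExclusionLog | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionLog]:
    """Remove rows with any present biomarker outside its closed interval.

    Returns (retained, excluded, log).  A present biomarker without a rule
    is a configuration error.
    """
    if log is None:
        log = ExclusionLog(n_input=len(participants))
    by_name = {r.biomarker: r for r in rules}
    out = pd.Series(False, index=participants.index)
    for name in ("fpg", "hba1c"):
        values = participants[name]
        if values.notna().any() and name not in by_name:
            raise CleaningConfigError(f"no RangeRule configured for biomarker {name!r}")
        if name in by_name:
            rule = by_name[name]
            out |= values.notna() & ((values < rule.lower) | (values > rule.upper))
    log.record(participants.loc[out, "participant_id"], "out_of_range")
    retained, excluded = participants[~out], participants[out]
    log.n_retained = len(retained)
    return retained, excluded, log


def convert_capillary(
    fpg_whole_blood, factor: float = CAPILLARY_TO_PLASMA_FACTOR
):
    """Convert capillary whole-blood glucose (mmol/L) to plasma-equivalent."""
    value = np.asarray(fpg_whole_blood, dtype=float)
    if np.any(value[~np.isnan(value)] <= 0):
        raise ValueError("glucose values must be positive")
    out = value * factor
    if np.isscalar(fpg_whole_blood) or np.ndim(fpg_whole_blood) == 0:
        return float(out)
    return out


def apply_capillary_conversion(
    participants: pd.DataFrame,
    studies: pd.DataFrame,
    factor: float = CAPILLARY_TO_PLASMA_FACTOR,
) -> pd.DataFrame:
    """Convert FPG for studies that measured capillary whole blood with
    devices that did not already report plasma-equivalent values."""
    needs = studies.loc[
        studies["fpg_capillary"] & ~studies["capillary_plasma_equivalent"], "study_id"
    ]
    out = participants.copy()
    mask = out["study_id"].isin(set(needs))
    out.loc[mask, "fpg"] = convert_capillary(out.loc[mask, "fpg"].to_numpy(), factor)
    return out


def lof_scores(points: np.ndarray, k: int = 100) -> np.ndarray:
    """Local-outlier-factor scores on z-standardized coordinates.

    Uses the standard LOF construction (k-distance, reachability distance,
    local reachability density) with Euclidean distances after per-axis
    z-standardization, so that the mmol/L axis does not dominate the % axis.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2:
        raise ValueError("LOF requires at least 2 points")
    k_eff = min(k, n - 1)
    std = pts.std(axis=0, ddof=0)
    std[std == 0] = 1.0
    z = (pts - pts.mean(axis=0)) / std
    lof = LocalOutlierFactor(n_neighbors=k_eff, algorithm="brute")
    lof.fit(z)
    return -lof.negative_outlier_factor_


def lof_filter(
    participants: pd.DataFrame,
    k: int = 100,
    ratio_threshold: float = 0.5,
    log: ExclusionLog | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, ExclusionLog]:
    """Remove implausible (FPG, HbA1c) pairs by the LOF density rule.

    A point is removed when its local reachability density is below
    ``ratio_threshold`` times the average density of its k nearest
    neighbors, which is algebraically the rule LOF > 1/ratio_threshold
    (ties at the boundary are retained).  Returns
    (retained, removed, scores, log).
    """
    if log is None:
        log = ExclusionLog(n_input=len(participants))
    if len(participants) < 2:
        warnings.warn("fewer than 2 points: LOF filter is a no-op")
        log.n_retained = len(participants)
        return participants, participants.iloc[0:0], np.ones(len(participants)), log
    pts = participants[["fpg", "hba1c"]].to_numpy(dtype=float)
    if np.isnan(pts).any():
        raise ValueError("LOF filter requires both biomarkers present on every row")
    scores = lof_scores(pts, k=k)
    removed_mask = scores > 1.0 / ratio_threshold
    log.record(participants.loc[removed_mask, "participant_id"], "implausible_pair")
    retained = participants[~removed_mask]
    log.n_retained = len(retained)
    return retained, participants[removed_mask], scores, log


def clean(
    participants: pd.DataFrame,
    studies: pd.DataFrame,
    rules=DEFAULT_RANGE_RULES,
    lof_k: int = 100,
    lof_ratio_threshold: float = 0.5,
    capillary_factor: float = CAPILLARY_TO_PLASMA_FACTOR,
    require_bmi: bool = False,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Full cleaning cascade in fixed order: exclusions -> range filter ->
    capillary conversion -> LOF filter (conversion precedes LOF so the joint
    distribution is on a common plasma-equivalent scale)."""
    log = ExclusionLog(n_input=len(participants))
    retained, log = apply_exclusions(
        participants, require_biomarkers=True, require_bmi=require_bmi, log=log
    )
    retained, _, log = range_filter(retained, rules, log=log)
    retained = apply_capillary_conversion(retained, studies, factor=capillary_factor)
    if len(retained) >= 2:
        retained, _, _, log = lof_filter(
            retained, k=lof_k, ratio_threshold=lof_ratio_threshold, log=log
        )
    log.n_retained = len(retained)
    return retained, log
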