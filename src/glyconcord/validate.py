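"""Study-holdout cross-validation and performance metrics.

Prediction equations are evaluated with grouped (study-level) tenfold
cross-validation repeated over several rounds: in each fold all data from a
random tenth of the studies are held out, the model is refitted on the
rest, and held-out individuals are predicted with the study random effect
set to zero (the held-out study is unseen).  Individual-level performance
is the C-statistic (concordance of predicted probabilities with outcomes,
ties counted one half); population-level performance is the mean error and
mean absolute error, in percentage points, between predicted and observed
prevalence across study x sex x age-group strata (18-39, 40-59, 60+).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .predeq import PredictionModelSpec, fit_prediction_model, predict_probability

AGE_GROUP_EDGES = (18.0, 40.0, 60.0, np.inf)
AGE_GROUP_LABELS = ("18-39", "40-59", "60+")


@dataclass
class FoldPlan:
    """Study-to-fold assignment for one cross-validation round."""

    round_index: int
    assignment: dict[str, int]  # study_id -> fold in 0..n_folds-1
    n_folds: int
    seed: int

    def holdout(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f == fold]


@dataclass
class CVReport:
    """Per-round metrics plus mean/range aggregates."""

    per_round: pd.DataFrame  # columns: round, c_statistic, mean_error, mean_abs_error
    summary: pd.DataFrame  # index metric, columns mean/min/max
    n_rounds: int
    n_folds: int
    skipped_folds: list[tuple[int, int]] = field(default_factory=list)


def make_folds(study_ids, n_folds: int = 10, seed: int = 0, round_index: int = 0) -> FoldPlan:
    """Random balanced partition of studies into folds (sizes differ by <= 1)."""
    ids = list(study_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("study_ids must be unique")
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} studies, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = np.arange(len(ids)) % n_folds
    assignment = {ids[int(i)]: int(f) for i, f in zip(perm, folds)}
    return FoldPlan(round_index=round_index, assignment=assignment, n_folds=n_folds, seed=seed)


def c_statistic(outcomes, probabilities) -> float:
    """Concordance statistic via the rank-sum (Mann-Whitney) identity.

    Equals the fraction of (positive, negative) pairs in which the positive
    has the higher predicted probability, ties counted 1/2.
    """
    y = np.asarray(outcomes, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("outcomes and probabilities must have the same length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("C-statistic undefined without both outcome classes")
    ranks = rankdata(p, method="average")
    u = np.sum(ranks[y == 1]) - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def age_group(ages) -> np.ndarray:
    ages = np.asarray(ages, dtype=float)
    idx = np.searchsorted(np.asarray(AGE_GROUP_EDGES[1:-1]), ages, side="right")
    if np.any(ages < AGE_GROUP_EDGES[0]):
        raise ValueError("ages below 18 cannot be assigned an adult age group")
    return np.asarray(AGE_GROUP_LABELS, dtype=object)[idx]


def prevalence_errors(
    probabilities,
    outcomes,
    strata: pd.DataFrame,
    min_stratum_size: int = 10,
    weighted: bool = False,
) -> tuple[float, float]:
    """Mean error and mean absolute error of predicted prevalence, in
    percentage points, across study x sex x age-group strata.

    Per stratum the predicted prevalence is the mean predicted probability
    and the observed prevalence the mean outcome.  Strata smaller than
    ``min_stratum_size`` are dropped with a warning; averaging across strata
    is unweighted by default (each stratum counts once).
    """
    df = strata.copy()
    df["p"] = np.asarray(probabilities, dtype=float)
    df["y"] = np.asarray(outcomes, dtype=float)
    keys = [c for c in ("study_id", "sex", "age_group") if c in df.columns]
    if not keys:
        raise ValueError("strata must define at least one of study_id/sex/age_group")
    grp = df.groupby(keys, observed=True).agg(
        pred=("p", "mean"), obs=("y", "mean"), n=("y", "size")
    )
    if len(grp) == 0:
        raise ValueError("no strata to evaluate")
    small = grp["n"] < min_stratum_size
    if small.all():
        raise ValueError("all strata are below the minimum size")
    if small.any():
        warnings.warn(f"dropping {int(small.sum())} strata below size {min_stratum_size}")
        grp = grp[~small]
    err = 100.0 * (grp["pred"] - grp["obs"])
    w = grp["n"] / grp["n"].sum() if weighted else None
    if weighted:
        return float(np.sum(w * err)), float(np.sum(w * err.abs()))
    return float(err.mean()), float(err.abs().mean())


def _round_seeds(seed: int, rounds: int) -> list[int]:
    ss = np.random.SeedSequence([seed, 97])
    return [int(s.generate_state(1, dtype=np.uint32)[0]) for s in ss.spawn(rounds)]


def cross_validate(
    spec: PredictionModelSpec,
    participants: pd.DataFrame,
    studies: pd.DataFrame,
    rounds: int = 20,
    n_folds: int = 10,
    seed: int = 0,
    min_stratum_size: int = 10,
) -> CVReport:
    """Repeated study-holdout cross-validation of one prediction equation.

    For each round, folds partition the studies; each fold's studies are
    held out once, the model is refitted on the remainder, and held-out
    rows are predicted with random effect 0.  Metrics are computed per
    round on the pooled held-out predictions.  A fold whose training
    outcome is constant is skipped with a warning.
    """
    study_ids = list(studies["study_id"])
    seeds = _round_seeds(seed, rounds)
    rows = []
    skipped: list[tuple[int, int]] = []
    merged = participants.merge(
        studies[["study_id", "region", "fpg_portable", "hba1c_portable"]],
        on="study_id",
        how="left",
    )
    for r in range(rounds):
        plan = make_folds(study_ids, n_folds=n_folds, seed=seeds[r], round_index=r)
        held_p, held_y, held_meta = [], [], []
        for fold in range(n_folds):
            out_ids = set(plan.holdout(fold))
            train = merged[~merged["study_id"].isin(out_ids)]
            test = merged[merged["study_id"].isin(out_ids)]
            if len(test) == 0:
                continue
            try:
                model = fit_prediction_model(spec, train, seed=seeds[r])
            except ValueError as exc:
                warnings.warn(f"round {r} fold {fold} skipped: {exc}")
                skipped.append((r, fold))
                continue
            if "outcome" in test.columns:
                y = test["outcome"].to_numpy(dtype=float)
            else:
                y = (
                    test[spec.target_biomarker] >= spec.target_threshold
                ).to_numpy(dtype=float)
            p = predict_probability(model, test)
            held_p.append(p)
            held_y.append(y)
            held_meta.append(test[["study_id", "sex", "age"]])
        p = np.concatenate(held_p)
        y = np.concatenate(held_y)
        meta = pd.concat(held_meta, ignore_index=True)
        strata = pd.DataFrame(
            {
                "study_id": meta["study_id"].to_numpy(),
                "sex": meta["sex"].to_numpy(),
                "age_group": age_group(meta["age"]),
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            me, mae = prevalence_errors(p, y, strata, min_stratum_size=min_stratum_size)
        rows.append(
            {
                "round": r,
                "c_statistic": c_statistic(y, p),
                "mean_error": me,
                "mean_abs_error": mae,
            }
        )
    per_round = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "mean": per_round[["c_statistic", "mean_error", "mean_abs_error"]].mean(),
            "min": per_round[["c_statistic", "mean_error", "mean_abs_error"]].min(),
            "max": per_round[["c_statistic", "mean_error", "mean_abs_error"]].max(),
        }
    )
    return CVReport(
        per_round=per_round,
        summary=summary,
        n_rounds=rounds,
        n_folds=n_folds,
        skipped_folds=skipped,
    )
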