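"""End-to-end orchestration: generate -> clean -> classify -> fit -> validate.

A single :class:`RunConfig` drives the whole analysis.  All randomness is
derived from one master seed; artifacts are delimited text and JSON with
stable contracts, so a rerun with the same configuration and seed produces
byte-identical outputs.

Units are fixed throughout: FPG in mmol/L, HbA1c in % (NGSP), BMI in
kg/m^2, age in years.  The loader can convert glucose from mg/dL
(divide by 18.016) and HbA1c from IFCC mmol/mol (NGSP% = 0.09148 x IFCC
+ 2.152) when the corresponding flag is set; otherwise off-unit inputs are
rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from .assoc import ASSOC_OUTCOMES, MCMCSettings, PriorSpec, build_design, fit_log_binomial, summarize_pr
from .cleaning import (
    CAPILLARY_TO_PLASMA_FACTOR,
    DEFAULT_RANGE_RULES,
    RangeRule,
    clean,
)
from .config import GeneratorConfig, default_generator_config
from .constants import PARTICIPANT_COLUMNS, SEX_VALUES, STUDY_COLUMNS
from .predeq import fit_prediction_model, probability_surface, registry_of_specs
from .synthetic import generate_cohort
from .validate import cross_validate

MGDL_PER_MMOL_L = 18.016
IFCC_TO_NGSP_SLOPE = 0.09148
IFCC_TO_NGSP_INTERCEPT = 2.152


class ParseError(ValueError):
    pass


def write_participants(records: pd.DataFrame, path) -> None:
    missing = [c for c in PARTICIPANT_COLUMNS if c not in records.columns]
    if missing:
        raise ParseError(f"participant table missing columns: {missing}")
    ordered = PARTICIPANT_COLUMNS + [
        c for c in records.columns if c not in PARTICIPANT_COLUMNS
    ]
    records[ordered].to_csv(path, index=False)


def load_participants(
    path, fpg_unit: str = "mmol_l", hba1c_unit: str = "ngsp_percent"
) -> pd.DataFrame:
    """Read a delimited participant table, validating schema and units."""
    df = pd.read_csv(path)
    missing = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"participant table missing columns: {missing}")
    bad_sex = ~df["sex"].isin(SEX_VALUES)
    if bad_sex.any():
        raise ParseError(
            f"sex outside {SEX_VALUES} at rows {df.index[bad_sex][:10].tolist()}"
        )
    if fpg_unit == "mg_dl":
        df["fpg"] = df["fpg"] / MGDL_PER_MMOL_L
    elif fpg_unit != "mmol_l":
        raise ParseError(f"unknown fpg_unit {fpg_unit!r}")
    if hba1c_unit == "ifcc_mmol_mol":
        df["hba1c"] = IFCC_TO_NGSP_SLOPE * df["hba1c"] + IFCC_TO_NGSP_INTERCEPT
    elif hba1c_unit != "ngsp_percent":
        raise ParseError(f"unknown hba1c_unit {hba1c_unit!r}")
    for col, lo, hi, what in (
        ("age", 0.0, 120.0, "age in years"),
        ("fpg", 0.2, 80.0, "FPG in mmol/L"),
        ("hba1c", 1.0, 25.0, "HbA1c in NGSP %"),
        ("bmi", 5.0, 120.0, "BMI in kg/m^2"),
    ):
        v = df[col]
        bad = v.notna() & ((v < lo) | (v > hi))
        if bad.any():
            raise ParseError(
                f"{col} values impossible for {what} at rows "
                f"{df.index[bad][:10].tolist()} (is a unit flag needed?)"
            )
    for col in ("diagnosed_previously", "on_glucose_lowering_medication", "pregnant"):
        df[col] = df[col].astype(bool)
    df["visit_index"] = df["visit_index"].astype(int)
    if (df["visit_index"] < 1).any():
        raise ParseError("visit_index must be >= 1")
    return df


def write_studies(studies: pd.DataFrame, path) -> None:
    studies.to_csv(path, index=False)


def load_studies(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"study table missing columns: {missing}")
    for col in ("fpg_portable", "hba1c_portable", "fpg_capillary", "capillary_plasma_equivalent"):
        df[col] = df[col].astype(bool)
    return df


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    generator: GeneratorConfig = field(default_factory=default_generator_config)
    participants_path: str | None = None  # external data instead of simulation
    studies_path: str | None = None
    # cleaning
    fpg_range: tuple[float, float] = (2.5, 30.0)
    hba1c_range: tuple[float, float] = (3.0, 18.0)
    lof_k: int = 100
    lof_ratio_threshold: float = 0.5
    capillary_factor: float = CAPILLARY_TO_PLASMA_FACTOR
    # study-subset sensitivity filters
    exclude_studies: tuple[str, ...] = ()
    exclude_capillary_studies: bool = False
    # association stage
    run_assoc: bool = True
    assoc_outcomes: tuple[str, ...] = tuple(ASSOC_OUTCOMES)
    prior_coef_sd: float = 10.0
    mcmc_chains: int = 4
    mcmc_burn_in: int = 800
    mcmc_retained_per_chain: int = 1500
    mcmc_thin: int = 1
    # prediction stage
    run_predict: bool = True
    directions: tuple[str, ...] = ("fpg_to_hba1c", "hba1c_to_fpg")
    prediction_model_ids: tuple[int, ...] = (8,)
    # validation stage
    run_validate: bool = True
    cv_rounds: int = 20
    cv_folds: int = 10
    cv_model_id: int = 2
    cv_direction: str = "fpg_to_hba1c"
    # master seed for every source of randomness
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            payload = yaml.safe_load(Path(source).read_text())
        else:
            payload = yaml.safe_load(source)
        return cls.from_dict(payload or {})

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        if "generator" in payload and not isinstance(payload["generator"], GeneratorConfig):
            payload["generator"] = GeneratorConfig.from_dict(payload["generator"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(payload) - known)
        if unknown:
            raise ParseError(f"unknown RunConfig fields: {unknown}")
        for name in (
            "exclude_studies",
            "assoc_outcomes",
            "directions",
            "prediction_model_ids",
            "fpg_range",
            "hba1c_range",
        ):
            if name in payload and payload[name] is not None:
                payload[name] = tuple(payload[name])
        return cls(**payload)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _stage(name):
    """Decorator-free stage guard: re-raise with the failing stage's name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    return _Ctx()


def run(config: RunConfig, outdir) -> Path:
    """Execute the configured stages; returns the run directory.

    Artifacts: participants/studies tables, ground-truth sidecar (when
    simulating), cleaned table + exclusion log, prevalence and composition
    tables, PR summaries, prediction-model coefficient files, surface
    tables, a cross-validation report, and a manifest with the
    configuration hash and per-stage seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def save_frame(df: pd.DataFrame, name: str, index: bool = False) -> None:
        df.to_csv(outdir / name, index=index)
        artifacts.append(name)

    def save_json(payload, name: str) -> None:
        (outdir / name).write_text(json.dumps(payload, indent=2, sort_keys=True))
        artifacts.append(name)

    with _stage("simulate"):
        if config.participants_path:
            participants = load_participants(config.participants_path)
            studies = load_studies(config.studies_path)
            truth = None
        else:
            gen = dataclasses.replace(config.generator, seed=config.stage_seed("simulate"))
            participants, studies, truth = generate_cohort(gen)
            save_json(
                {
                    "study_effects": truth.study_effects,
                    "n_participants": int(len(truth.table)),
                },
                "ground_truth_summary.json",
            )
            truth.table.to_csv(outdir / "ground_truth.csv")
            artifacts.append("ground_truth.csv")
        write_participants(participants, outdir / "participants.csv")
        write_studies(studies, outdir / "studies.csv")
        artifacts += ["participants.csv", "studies.csv"]

    with _stage("subset"):
        drop = set(config.exclude_studies)
        if config.exclude_capillary_studies:
            drop |= set(studies.loc[studies["fpg_capillary"], "study_id"])
        if drop:
            studies = studies[~studies["study_id"].isin(drop)]
            participants = participants[~participants["study_id"].isin(drop)]

    with _stage("clean"):
        rules = (
            RangeRule("fpg", *config.fpg_range),
            RangeRule("hba1c", *config.hba1c_range),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cleaned, log = clean(
                participants,
                studies,
                rules=rules,
                lof_k=config.lof_k,
                lof_ratio_threshold=config.lof_ratio_threshold,
                capillary_factor=config.capillary_factor,
            )
        write_participants(cleaned, outdir / "cleaned.csv")
        artifacts.append("cleaned.csv")
        save_json(log.to_dict(), "exclusion_log.json")

    with _stage("classify"):
        table = _classify.prevalence_table(cleaned, studies)
        save_frame(table, "prevalence.csv")
        categories = _classify.classify_frame(cleaned)
        comp = _classify.composition_of_screen_detected(cleaned, categories=categories)
        save_frame(comp.reset_index(names="scale"), "screen_detected_composition.csv")
        merged = cleaned.merge(studies[["study_id", "region"]], on="study_id")
        corr = {
            region: _classify.biomarker_correlation(grp)
            for region, grp in merged.groupby("region")
        }
        corr["all_studies"] = _classify.biomarker_correlation(merged)
        save_json(corr, "biomarker_correlation.json")

    if config.run_assoc:
        with _stage("assoc"):
            priors = PriorSpec(coef_sd=config.prior_coef_sd)
            mcmc = MCMCSettings(
                chains=config.mcmc_chains,
                burn_in=config.mcmc_burn_in,
                retained_per_chain=config.mcmc_retained_per_chain,
                thin=config.mcmc_thin,
                seed=config.stage_seed("assoc"),
            )
            for outcome in config.assoc_outcomes:
                design = build_design(cleaned, studies, outcome, categories=categories)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = fit_log_binomial(design, priors, mcmc)
                save_frame(summarize_pr(fit), f"pr_summary_{outcome}.csv")

    if config.run_predict:
        with _stage("predict"):
            for direction in config.directions:
                specs = {s.model_id: s for s in registry_of_specs(direction)}
                for model_id in config.prediction_model_ids:
                    model = fit_prediction_model(
                        specs[model_id],
                        cleaned,
                        studies,
                        seed=config.stage_seed(f"predict:{direction}:{model_id}"),
                    )
                    name = f"prediction_model_{direction}_{model_id}.json"
                    model.to_json(outdir / name)
                    artifacts.append(name)
                    surface = probability_surface(model)
                    save_frame(surface, f"surface_{direction}_{model_id}.csv")

    if config.run_validate:
        with _stage("validate"):
            spec = {
                s.model_id: s
                for s in registry_of_specs(config.cv_direction)
            }[config.cv_model_id]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = cross_validate(
                    spec,
                    cleaned,
                    studies,
                    rounds=config.cv_rounds,
                    n_folds=config.cv_folds,
                    seed=config.stage_seed("validate"),
                )
            save_frame(report.per_round, "cv_per_round.csv")
            save_frame(report.summary, "cv_summary.csv", index=True)

    with _stage("manifest"):
        manifest = {
            "config_hash": config.config_hash(),
            "master_seed": config.seed,
            "stage_seeds": {
                s: config.stage_seed(s) for s in ("simulate", "assoc", "validate")
            },
            "artifacts": sorted(set(artifacts)),
        }
        save_json(manifest, "manifest.json")
    return outdir
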