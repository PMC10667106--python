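"""Logistic prediction equations between FPG and HbA1c.

Nine registered mixed-effects logistic model specifications estimate, for a
person without previously diagnosed diabetes, the probability that the
unmeasured glycemic biomarker exceeds its diagnostic threshold (HbA1c >=
6.5% given FPG, or FPG >= 7.0 mmol/L given HbA1c).  The specifications
differ in which predictors they include (sex, age, measurement method,
region intercepts, BMI) and whether the conditioning-biomarker coefficient
varies by region and/or sex; every model includes a study-level random
intercept.  Age enters as a continuous covariate and the biomarker enters
linearly.

Fitting maximizes an approximate marginal likelihood: a joint penalized
Newton step on (fixed effects, study intercepts) with the random-intercept
variance updated by a Laplace EM step.  Predictions for new individuals or
studies use a random effect of zero (the population-median study) unless a
value is supplied.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .constants import FPG_THRESHOLD, HBA1C_THRESHOLD
from .regions import Region, REFERENCE_REGION

DIRECTIONS = ("fpg_to_hba1c", "hba1c_to_fpg")

#: Fixed reference levels at which the conditioning biomarker is centered in
#: the design (FPG mmol/L, HbA1c %).  Centering at a constant keeps region
#: intercepts interpretable (the log-odds at a typical biomarker level
#: rather than at an extrapolated zero), conditions the region
#: intercept-slope blocks, and, being a constant, introduces no
#: training-data dependence into cross-validation.
BIOMARKER_CENTER = {"fpg": 5.5, "hba1c": 5.5}

#: Fixed reference covariate levels (age in years, BMI in kg/m^2) at which
#: age and BMI are centered in the design, for the same reasons.
AGE_CENTER = 50.0
BMI_CENTER = 27.0


class PredictionInputError(ValueError):
    pass


@dataclass(frozen=True)
class PredictionModelSpec:
    """One of the nine registered prediction-equation structures."""

    model_id: int
    direction: str
    include_sex: bool = False
    include_age: bool = False
    include_method: bool = False
    include_region_intercepts: bool = False
    include_bmi: bool = False
    region_specific_slope: bool = False
    sex_specific_slope: bool = False
    #: "deviation": global intercept/slope plus non-reference region terms;
    #: "nested": one intercept and one slope per region (same column span).
    region_parameterization: str = "deviation"

    @property
    def conditioning_biomarker(self) -> str:
        return "fpg" if self.direction == "fpg_to_hba1c" else "hba1c"

    @property
    def target_biomarker(self) -> str:
        return "hba1c" if self.direction == "fpg_to_hba1c" else "fpg"

    @property
    def target_threshold(self) -> float:
        return HBA1C_THRESHOLD if self.direction == "fpg_to_hba1c" else FPG_THRESHOLD


def registry_of_specs(direction: str) -> list[PredictionModelSpec]:
    """The nine model structures, identical for both directions.

    1. biomarker only; 2. + sex + age; 3. + sex + age + method;
    4. + sex + age + method + region intercepts; 5. model 4 + BMI +
    region-specific biomarker slope; 6. model 5 + sex-specific slope;
    7. model 4 + region-specific slope without BMI; 8. model 5 with the
    region terms re-expressed as per-region intercept and slope;
    9. model 8 + sex-specific slope.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")

    def spec(model_id, **kw):
        return PredictionModelSpec(model_id=model_id, direction=direction, **kw)

    base = dict(include_sex=True, include_age=True)
    full = dict(include_sex=True, include_age=True, include_method=True,
                include_region_intercepts=True)
    return [
        spec(1),
        spec(2, **base),
        spec(3, **base, include_method=True),
        spec(4, **full),
        spec(5, **full, include_bmi=True, region_specific_slope=True),
        spec(6, **full, include_bmi=True, region_specific_slope=True,
             sex_specific_slope=True),
        spec(7, **full, region_specific_slope=True),
        spec(8, **full, include_bmi=True, region_specific_slope=True,
             region_parameterization="nested"),
        spec(9, **full, include_bmi=True, region_specific_slope=True,
             sex_specific_slope=True, region_parameterization="nested"),
    ]


_REGION_ORDER = [r.value for r in Region]


def _merged(participants: pd.DataFrame, studies: pd.DataFrame | None) -> pd.DataFrame:
    need_meta = ("region" not in participants.columns) or (
        "fpg_portable" not in participants.columns
    )
    if need_meta and studies is not None:
        participants = participants.merge(
            studies[["study_id", "region", "fpg_portable", "hba1c_portable"]],
            on="study_id",
            how="left",
        )
    return participants


def design_matrix(
    spec: PredictionModelSpec,
    participants: pd.DataFrame,
    studies: pd.DataFrame | None = None,
    regions: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the fixed-effects design for a spec.

    ``regions`` pins the region level set (needed when predicting from a
    fitted model); by default the regions present in the data are used, in
    canonical region order.  Raises :class:`PredictionInputError` naming any
    missing required covariate.
    """
    rows = _merged(participants, studies)
    bio = spec.conditioning_biomarker
    required = [bio]
    if spec.include_sex or spec.sex_specific_slope:
        required.append("sex")
    if spec.include_age:
        required.append("age")
    if spec.include_bmi:
        required.append("bmi")
    if spec.include_method:
        required.append(f"{bio}_portable")
    needs_region = spec.include_region_intercepts or spec.region_specific_slope
    if needs_region:
        required.append("region")
    for name in required:
        if name not in rows.columns:
            raise PredictionInputError(f"missing required covariate {name!r}")
        if rows[name].isna().any():
            raise PredictionInputError(f"required covariate {name!r} has missing values")

    x = rows[bio].to_numpy(dtype=float) - BIOMARKER_CENTER[bio]
    male = (rows["sex"] == "male").to_numpy(dtype=float) if "sex" in rows else None
    cols: dict[str, np.ndarray] = {}
    if needs_region:
        present = [r for r in _REGION_ORDER if (rows["region"] == r).any()]
        if regions is None:
            regions = present
        unknown = sorted(set(present) - set(regions))
        if unknown:
            raise PredictionInputError(f"regions not in the fitted model: {unknown}")
        dummies = {r: (rows["region"] == r).to_numpy(dtype=float) for r in regions}

    if spec.region_parameterization == "nested" and needs_region:
        for r in regions:
            cols[f"intercept[{r}]"] = dummies[r]
        for r in regions:
            cols[f"{bio}[{r}]"] = dummies[r] * x
    else:
        cols["intercept"] = np.ones(len(rows))
        cols[bio] = x
        if spec.include_region_intercepts and needs_region:
            for r in regions:
                if r != REFERENCE_REGION.value:
                    cols[f"region_{r}"] = dummies[r]
        if spec.region_specific_slope and needs_region:
            for r in regions:
                if r != REFERENCE_REGION.value:
                    cols[f"{bio}_x_region_{r}"] = dummies[r] * x
    if spec.sex_specific_slope:
        cols[f"{bio}_x_male"] = male * x
    if spec.include_sex:
        cols["male"] = male
    if spec.include_age:
        cols["age10"] = (rows["age"].to_numpy(dtype=float) - AGE_CENTER) / 10.0
    if spec.include_bmi:
        cols["bmi5"] = (rows["bmi"].to_numpy(dtype=float) - BMI_CENTER) / 5.0
    if spec.include_method:
        cols["method_portable"] = rows[f"{bio}_portable"].to_numpy(dtype=float)

    names = list(cols)
    return np.column_stack([cols[n] for n in names]), names


@dataclass
class FittedPredictionModel:
    """Coefficients and variance components of one fitted prediction model."""

    spec: PredictionModelSpec
    coefficients: dict[str, float]
    re_variance: float
    regions: list[str] | None
    study_effects: dict[str, float]
    deviance: float
    converged: bool
    n_obs: int
    data_hash: str
    seed: int

    def to_json(self, path=None) -> str:
        payload = {
            "spec": asdict(self.spec),
            "coefficients": self.coefficients,
            "re_variance": self.re_variance,
            "regions": self.regions,
            "study_effects": self.study_effects,
            "deviance": self.deviance,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "data_hash": self.data_hash,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FittedPredictionModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        payload["spec"] = PredictionModelSpec(**payload["spec"])
        return cls(**payload)


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _fit_penalized(X, y, g, J, init_sigma2=0.1, max_outer=200, tol=1e-8):
    """Joint penalized Newton on (beta, u) with Laplace EM for sigma^2.

    Uses a Schur-complement solve so cost scales with the number of fixed
    effects, not the number of studies.
    """
    n, p = X.shape
    beta = np.zeros(p)
    u = np.zeros(J)
    sigma2 = init_sigma2
    converged = False

    def pen_ll(beta, u, sigma2):
        eta = X @ beta + u[g]
        return _bernoulli_loglik(eta, y) - 0.5 * np.sum(u**2) / sigma2

    for outer in range(max_outer):
        # inner Newton for the joint mode of (beta, u) at fixed sigma2
        for _ in range(60):
            eta = X @ beta + u[g]
            mu = expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            r = y - mu
            gbeta = X.T @ r
            gu = np.bincount(g, weights=r, minlength=J) - u / sigma2
            A = (X * w[:, None]).T @ X
            B = np.zeros((J, p))
            np.add.at(B, g, w[:, None] * X)
            D = np.bincount(g, weights=w, minlength=J) + 1.0 / sigma2
            S = A - B.T @ (B / D[:, None]) + 1e-10 * np.eye(p)
            rhs = gbeta - B.T @ (gu / D)
            db = np.linalg.solve(S, rhs)
            du = (gu - B @ db) / D
            base = pen_ll(beta, u, sigma2)
            step = 1.0
            while step > 1e-6:
                nb, nu = beta + step * db, u + step * du
                if pen_ll(nb, nu, sigma2) >= base - 1e-12:
                    break
                step *= 0.5
            beta, u = nb, nu
            if step * max(np.max(np.abs(db)), np.max(np.abs(du)), 0.0) < 1e-10:
                break
        # Laplace EM update of the random-intercept variance
        eta = X @ beta + u[g]
        w = np.clip(expit(eta) * (1 - expit(eta)), 1e-10, None)
        D = np.bincount(g, weights=w, minlength=J) + 1.0 / sigma2
        new_sigma2 = float(np.mean(u**2 + 1.0 / D))
        new_sigma2 = max(new_sigma2, 1e-8)
        if abs(new_sigma2 - sigma2) < tol * (sigma2 + 1e-6):
            sigma2 = new_sigma2
            converged = True
            break
        sigma2 = new_sigma2
    # Laplace-approximate marginal deviance: -2 x [conditional log-likelihood
    # at the mode, minus the random-effect penalty, minus the Gaussian
    # curvature correction].  A proper objective, so a richer nested model
    # never has (materially) higher deviance.
    eta = X @ beta + u[g]
    w = np.clip(expit(eta) * (1 - expit(eta)), 1e-10, None)
    D = np.bincount(g, weights=w, minlength=J) + 1.0 / sigma2
    ll_marg = (
        _bernoulli_loglik(eta, y)
        - 0.5 * np.sum(u**2) / sigma2
        - 0.5 * np.sum(np.log(sigma2 * D))
    )
    return beta, u, sigma2, -2.0 * ll_marg, converged


def fit_prediction_model(
    spec: PredictionModelSpec,
    participants: pd.DataFrame,
    studies: pd.DataFrame | None = None,
    seed: int = 0,
) -> FittedPredictionModel:
    """Fit one prediction equation on participants without diagnosed diabetes.

    The outcome is the indicator that the target biomarker is at or above
    its diagnostic threshold; a precomputed 0/1 ``outcome`` column takes
    precedence when present (used by simulators whose target biomarker is
    latent).  Rows with a previous diagnosis or on glucose-lowering
    medication are dropped.  Fitting is deterministic; ``seed`` is recorded
    in the metadata for provenance only.
    """
    rows = _merged(participants, studies)
    dx = rows["diagnosed_previously"].astype(bool) | rows[
        "on_glucose_lowering_medication"
    ].astype(bool)
    rows = rows[~dx]
    if "outcome" in rows.columns:
        y = rows["outcome"].to_numpy(dtype=float)
    else:
        target = rows[spec.target_biomarker]
        if target.isna().any():
            raise PredictionInputError(
                f"target biomarker {spec.target_biomarker!r} has missing values"
            )
        y = (target >= spec.target_threshold).to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError(
            f"outcome is constant ({int(y[0])}) in the training data; "
            "the model is not identifiable"
        )
    X, names = design_matrix(spec, rows)
    needs_region = spec.include_region_intercepts or spec.region_specific_slope
    regions = None
    if needs_region:
        regions = [r for r in _REGION_ORDER if (rows["region"] == r).any()]
    g, study_ids = pd.factorize(rows["study_id"])
    beta, u, sigma2, deviance, converged = _fit_penalized(X, y, g, len(study_ids))
    if not converged:
        warnings.warn("prediction-model fit did not reach the variance fixed point")
    digest = hashlib.sha256(
        pd.util.hash_pandas_object(rows[["study_id"]], index=False).to_numpy().tobytes()
        + X.tobytes()
        + y.tobytes()
    ).hexdigest()[:16]
    return FittedPredictionModel(
        spec=spec,
        coefficients={n: float(b) for n, b in zip(names, beta)},
        re_variance=float(sigma2),
        regions=regions,
        study_effects={str(s): float(v) for s, v in zip(study_ids, u)},
        deviance=float(deviance),
        converged=bool(converged),
        n_obs=int(len(y)),
        data_hash=digest,
        seed=int(seed),
    )


def predict_probability(
    model: FittedPredictionModel,
    covariates: pd.DataFrame | dict,
    studies: pd.DataFrame | None = None,
    random_effect: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Predicted probability that the target biomarker exceeds its threshold.

    ``covariates`` may be a participant-style frame (merged with ``studies``
    if region/method columns are absent) or a single-row mapping.  The study
    random effect defaults to 0, the population-median study.
    """
    if isinstance(covariates, dict):
        covariates = pd.DataFrame([covariates])
    X, names = design_matrix(
        model.spec, covariates, studies, regions=model.regions
    )
    beta = np.array([model.coefficients[n] for n in names])
    eta = X @ beta + random_effect
    return expit(eta)


def _representative(lo: float, hi: float, fallback_width: float) -> float:
    if np.isfinite(hi):
        return 0.5 * (lo + hi)
    return lo + 0.5 * fallback_width


def probability_surface(
    model: FittedPredictionModel,
    sexes=("female", "male"),
    age_bands=((18, 40), (40, 60), (60, np.inf)),
    regions=None,
    bmi_bands=((15, 25), (25, 30), (30, np.inf)),
    biomarker_bins=None,
    method_portable: bool = False,
) -> pd.DataFrame:
    """Tabulate predictions over a sex x age x region x BMI x biomarker grid.

    Each cell is evaluated at representative covariate values: bin midpoints
    for the biomarker, band midpoints for age and BMI (open-ended bands at
    the lower edge plus half the previous band's width, e.g. BMI >= 30 at
    32.5), with the random effect at 0.
    """
    bio = model.spec.conditioning_biomarker
    if regions is None:
        regions = model.regions or [REFERENCE_REGION.value]
    if biomarker_bins is None:
        if bio == "fpg":
            biomarker_bins = ((4.5, 5.0), (5.0, 5.5), (5.5, 6.0), (6.0, 6.5), (6.5, 7.0))
        else:
            biomarker_bins = ((5.0, 5.4), (5.4, 5.8), (5.8, 6.1), (6.1, 6.5))
    grids = [tuple(sexes), tuple(age_bands), tuple(regions), tuple(bmi_bands), tuple(biomarker_bins)]
    if any(len(gr) == 0 for gr in grids):
        raise ValueError("empty surface grid")

    def width(bands):
        finite = [hi - lo for lo, hi in bands if np.isfinite(hi)]
        return finite[-1] if finite else 10.0

    rows = []
    for sex in sexes:
        for a_lo, a_hi in age_bands:
            for region in regions:
                for b_lo, b_hi in bmi_bands:
                    for x_lo, x_hi in biomarker_bins:
                        rows.append(
                            {
                                "sex": sex,
                                "age_band": f"{a_lo:g}-{a_hi:g}",
                                "region": region,
                                "bmi_band": f"{b_lo:g}-{b_hi:g}",
                                f"{bio}_bin": f"{x_lo:g}-{x_hi:g}",
                                "age": _representative(a_lo, a_hi, width(age_bands)),
                                "bmi": _representative(b_lo, b_hi, width(bmi_bands)),
                                bio: 0.5 * (x_lo + x_hi),
                            }
                        )
    grid = pd.DataFrame(rows)
    cov = grid[["sex", "age", "bmi", bio]].copy()
    cov["region"] = grid["region"]
    cov["fpg_portable"] = method_portable
    cov["hba1c_portable"] = method_portable
    grid["probability"] = predict_probability(model, cov)
    return grid
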