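"""Bayesian log-binomial regressions for the composition of screen-detected
diabetes.

Three separate log-link binomial regressions relate, among participants
with screen-detected diabetes, the binary indicator of each manifestation
(isolated elevated FPG, isolated elevated HbA1c, elevated levels of both)
to individual covariates (sex, age per decade, BMI per 5 kg/m^2) and study
characteristics (region, study mid-year per 5 years, percent of people with
diabetes previously diagnosed per 10 percentage points, FPG and HbA1c
measurement method), with a study-level random intercept:

    y_i ~ Bernoulli(p_i),   log p_i = x_i' beta + u_{study(i)},
    u_j ~ Normal(0, sigma_u^2),

so exp(beta_k) is a prevalence ratio (PR).  The log link requires p_i <= 1;
parameter states implying a fitted probability above 1 for any observed row
have zero likelihood and are rejected by the sampler.

Priors: Normal(0, sd = 10) on the coefficients and Uniform(0.01, 2.00) on
sigma_u.  (A much tighter Normal(0, sd = 0.01) coefficient prior would rule
out routinely observed PRs far from 1 - for instance PR 0.24 is about 143
such prior standard deviations from zero - and corresponds to reading the
common precision-0.01 parameterization of BUGS-family engines as an sd, so
the sd-10 prior is the default; any scale can be configured.)

Posterior sampling uses an adaptive random-walk Metropolis-within-Gibbs
scheme: a joint adaptive-covariance proposal for beta, per-study scalar
proposals for the random effects, and an exact truncated inverse-gamma
Gibbs draw for sigma_u^2.  Convergence is monitored with split R-hat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invgamma

from .classify import classify_frame, GlycemicCategory, SCREEN_DETECTED
from .regions import REFERENCE_REGION, Region

ASSOC_OUTCOMES = {
    "isolated_fpg": GlycemicCategory.ISOLATED_ELEVATED_FPG,
    "isolated_hba1c": GlycemicCategory.ISOLATED_ELEVATED_HBA1C,
    "both_elevated": GlycemicCategory.BOTH_ELEVATED,
}


@dataclass
class AssocDesign:
    """Numeric design for one log-binomial regression."""

    outcome: str
    X: np.ndarray  # (n, p) including the leading intercept column
    y: np.ndarray  # (n,) binary
    columns: list[str]
    study_index: np.ndarray  # (n,) codes 0..J-1
    study_ids: list[str]


@dataclass
class PriorSpec:
    coef_sd: float = 10.0
    re_sd_bounds: tuple[float, float] = (0.01, 2.00)

    def validate(self) -> None:
        if self.coef_sd <= 0:
            raise ValueError("coef_sd must be > 0")
        lo, hi = self.re_sd_bounds
        if not 0 < lo < hi:
            raise ValueError("re_sd_bounds must satisfy 0 < low < high")


@dataclass
class MCMCSettings:
    chains: int = 4
    burn_in: int = 5000
    retained_per_chain: int = 12500
    thin: int = 1
    seed: int = 0
    rhat_threshold: float = 1.05
    store_u: bool = False  # keep per-draw random effects (audit/testing)

    @classmethod
    def reduced(cls, seed: int = 0) -> "MCMCSettings":
        """Short chains for desk-scale simulation checks."""
        return cls(chains=4, burn_in=1000, retained_per_chain=2000, thin=1, seed=seed)


@dataclass
class AssocFit:
    """Posterior draws and summaries from one log-binomial regression."""

    outcome: str
    columns: list[str]
    beta_draws: np.ndarray  # (chains, n_retained, p)
    sigma_draws: np.ndarray  # (chains, n_retained)
    u_mean: np.ndarray  # posterior mean random effect per study
    study_ids: list[str]
    rhat: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    accept_rates: dict[str, float] = field(default_factory=dict)
    u_draws: np.ndarray | None = None  # (chains, n_retained, J) when stored

    @property
    def n_retained_total(self) -> int:
        return int(self.beta_draws.shape[0] * self.beta_draws.shape[1])

    def flat_beta(self) -> np.ndarray:
        return self.beta_draws.reshape(-1, self.beta_draws.shape[-1])

    def max_linear_predictor(self, design: "AssocDesign", chunk: int = 256) -> np.ndarray:
        """Per-draw maximum of x_i'beta + u_study(i) over observed rows.

        Requires the fit to have stored random-effect draws; used to audit
        the log-binomial p <= 1 constraint.  Evaluated in draw chunks to
        bound memory.
        """
        if self.u_draws is None:
            raise ValueError("fit was run without store_u; no u draws available")
        flat_beta = self.flat_beta()
        flat_u = self.u_draws.reshape(-1, self.u_draws.shape[-1])
        out = np.empty(len(flat_beta))
        for start in range(0, len(flat_beta), chunk):
            sl = slice(start, start + chunk)
            eta = design.X @ flat_beta[sl].T + flat_u[sl].T[design.study_index, :]
            out[sl] = eta.max(axis=0)
        return out


def percent_previously_diagnosed(participants: pd.DataFrame) -> pd.Series:
    """Per-study percentage of people with diabetes (any category) who had
    been previously diagnosed, computed from the full study sample."""
    categories = classify_frame(participants)
    has_diabetes = categories != GlycemicCategory.NO_DIABETES.value
    diagnosed = categories == GlycemicCategory.DIAGNOSED.value
    grp = pd.DataFrame(
        {"study_id": participants["study_id"], "dm": has_diabetes, "dx": diagnosed}
    ).groupby("study_id")
    agg = grp.sum()
    out = pd.Series(np.nan, index=agg.index, name="pct_diagnosed")
    nonzero = agg["dm"] > 0
    out[nonzero] = 100.0 * agg.loc[nonzero, "dx"] / agg.loc[nonzero, "dm"]
    return out


def build_design(
    participants: pd.DataFrame,
    studies: pd.DataFrame,
    outcome: str,
    categories: pd.Series | None = None,
) -> AssocDesign:
    """Restrict to screen-detected participants and assemble the design.

    Scalings follow the reporting convention: age per 10 years, BMI per
    5 kg/m^2, study mid-year per 5 years (centered at 2010), percent
    previously diagnosed per 10 percentage points.  Region indicators use
    the high-income western region as reference.  Studies with zero
    participants with diabetes (no defined percent diagnosed) are dropped
    with a warning.
    """
    if outcome not in ASSOC_OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {sorted(ASSOC_OUTCOMES)}")
    if categories is None:
        categories = classify_frame(participants)
    pct = percent_previously_diagnosed(participants)

    screen = categories.isin([c.value for c in SCREEN_DETECTED])
    rows = participants[screen].copy()
    rows["category"] = categories[screen]
    meta_cols = ["study_id", "region", "mid_year", "fpg_portable", "hba1c_portable"]
    rows = rows.merge(studies[meta_cols], on="study_id", how="left")
    rows = rows.merge(pct.rename("pct_diagnosed"), left_on="study_id", right_index=True)

    no_diabetes = sorted(
        set(studies["study_id"]) - set(pct.index[pct.notna()])
    )
    if no_diabetes:
        warnings.warn(
            "excluding studies with no participants with diabetes (percent "
            f"previously diagnosed undefined): {no_diabetes}"
        )
    undefined = rows["pct_diagnosed"].isna()
    rows = rows[~undefined]
    missing_bmi = rows["bmi"].isna()
    if missing_bmi.any():
        warnings.warn(f"dropping {int(missing_bmi.sum())} rows with missing BMI")
        rows = rows[~missing_bmi]
    if len(rows) == 0:
        raise ValueError("no screen-detected rows available for the design")

    y = (rows["category"] == ASSOC_OUTCOMES[outcome].value).to_numpy(dtype=int)
    if y.min() == y.max():
        raise ValueError(
            f"outcome {outcome!r} is constant ({y[0]}) among screen-detected rows; "
            "the regression is not identifiable"
        )

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(rows))}
    cols["male"] = (rows["sex"] == "male").to_numpy(dtype=float)
    cols["age10"] = rows["age"].to_numpy(dtype=float) / 10.0
    cols["bmi5"] = rows["bmi"].to_numpy(dtype=float) / 5.0
    region_order = [r.value for r in Region if r is not REFERENCE_REGION]
    for region in region_order:
        if (rows["region"] == region).any():
            cols[f"region_{region}"] = (rows["region"] == region).to_numpy(dtype=float)
    cols["year5"] = (rows["mid_year"].to_numpy(dtype=float) - 2010.0) / 5.0
    cols["pct_diag10"] = rows["pct_diagnosed"].to_numpy(dtype=float) / 10.0
    cols["fpg_portable"] = rows["fpg_portable"].to_numpy(dtype=float)
    cols["hba1c_portable"] = rows["hba1c_portable"].to_numpy(dtype=float)
    # Drop constant non-intercept columns (e.g. no portable-device study).
    names = ["intercept"] + [
        k for k in cols if k != "intercept" and np.ptp(cols[k]) > 0
    ]
    X = np.column_stack([cols[k] for k in names])

    study_codes, study_ids = pd.factorize(rows["study_id"])
    return AssocDesign(
        outcome=outcome,
        X=X,
        y=y,
        columns=names,
        study_index=study_codes,
        study_ids=list(study_ids),
    )


def _row_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-row Bernoulli log likelihood under the log link; -inf rows where
    the p <= 1 constraint is violated."""
    out = np.where(y == 1, eta, np.where(eta < 0, np.log(-np.expm1(np.minimum(eta, -1e-300))), -np.inf))
    out[eta >= 0] = -np.inf
    return out


def _split_rhat(chains: np.ndarray) -> float:
    """Split R-hat of Gelman et al. for draws shaped (chains, n)."""
    m, n = chains.shape
    half = n // 2
    if half < 2:
        return np.nan
    segs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    means = segs.mean(axis=1)
    variances = segs.var(axis=1, ddof=1)
    W = variances.mean()
    B = half * means.var(ddof=1)
    if W <= 0:
        return 1.0
    return float(np.sqrt((half - 1) / half + B / (W * half)))


def _run_chain(
    design: AssocDesign, priors: PriorSpec, mcmc: MCMCSettings, chain_seed: int
):
    rng = np.random.default_rng(chain_seed)
    X, y, g = design.X, design.y, design.study_index
    n, p = X.shape
    J = len(design.study_ids)
    lo_sd, hi_sd = priors.re_sd_bounds

    # Start at an interior state: intercept at the log event rate, others 0.
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-3)) - 0.1
    u = np.zeros(J)
    sigma = 0.5 * (lo_sd + hi_sd) / 2

    eta = X @ beta + u[g]
    ll_rows = _row_loglik(eta, y)
    ll = ll_rows.sum()

    def beta_logprior(b):
        return -0.5 * np.sum(b**2) / priors.coef_sd**2

    lp_beta = beta_logprior(beta)

    n_iter = mcmc.burn_in + mcmc.retained_per_chain * mcmc.thin
    beta_out = np.empty((mcmc.retained_per_chain, p))
    sigma_out = np.empty(mcmc.retained_per_chain)
    u_sum = np.zeros(J)
    u_out = np.empty((mcmc.retained_per_chain, J)) if mcmc.store_u else None

    # Adaptive joint proposal for beta (Haario-style empirical covariance
    # with Robbins-Monro scale tuning), per-study scalar proposals for u.
    # The proposal covariance starts at the inverse Fisher information of
    # the log-link Bernoulli model at the initial state, which captures the
    # strong correlation between the intercept and uncentered covariates.
    log_scale = np.log(2.38 / np.sqrt(p))
    mu0 = np.exp(np.clip(eta, None, -1e-6))
    fisher = (X * (mu0 / (1.0 - mu0))[:, None]).T @ X + 1e-8 * np.eye(p)
    chol = np.linalg.cholesky(np.linalg.inv(fisher))
    hist = np.empty((min(mcmc.burn_in, 4000), p))
    u_scales = np.full(J, 0.1)
    acc_beta = acc_u = 0
    n_u_tries = 0
    kept = 0

    for it in range(n_iter):
        adapting = it < mcmc.burn_in

        # --- beta block ---
        delta = np.exp(log_scale) * (chol @ rng.standard_normal(p))
        beta_prop = beta + delta
        eta_prop = eta + X @ delta
        ll_rows_prop = _row_loglik(eta_prop, y)
        ll_prop = ll_rows_prop.sum()
        lp_prop = beta_logprior(beta_prop)
        log_alpha = (ll_prop + lp_prop) - (ll + lp_beta)
        accepted = np.log(rng.random()) < log_alpha
        if accepted:
            beta, eta, ll_rows, ll, lp_beta = beta_prop, eta_prop, ll_rows_prop, ll_prop, lp_prop
            acc_beta += 1
        if adapting:
            hist[it % len(hist)] = beta
            log_scale += (0.6 if accepted else -0.25) / np.sqrt(1 + it // 10)
            if it >= 200 and it % 200 == 0:
                cov = np.atleast_2d(np.cov(hist[: min(it + 1, len(hist))].T)) + 1e-8 * np.eye(p)
                chol = np.linalg.cholesky(cov)

        # --- u block: independent per-study scalar proposals ---
        du = u_scales * rng.standard_normal(J)
        eta_prop = eta + du[g]
        ll_rows_prop = _row_loglik(eta_prop, y)
        d_ll = np.bincount(g, ll_rows_prop - ll_rows, minlength=J)
        d_ll = np.where(np.isnan(d_ll), -np.inf, d_ll)
        u_prop = u + du
        d_prior = -0.5 * (u_prop**2 - u**2) / sigma**2
        acc_mask = np.log(rng.random(J)) < d_ll + d_prior
        if acc_mask.any():
            u = np.where(acc_mask, u_prop, u)
            keep_rows = acc_mask[g]
            eta = np.where(keep_rows, eta_prop, eta)
            ll_rows = np.where(keep_rows, ll_rows_prop, ll_rows)
            ll = ll_rows.sum()
        acc_u += int(acc_mask.sum())
        n_u_tries += J
        if adapting:
            u_scales *= np.exp(np.where(acc_mask, 0.3, -0.18) / np.sqrt(1 + it // 10))
            u_scales = np.clip(u_scales, 1e-4, 2.0)

        # --- sigma: exact Gibbs draw, Uniform(lo, hi) prior on the sd ---
        S = float(np.sum(u**2))
        shape = (J - 1) / 2.0
        if S > 0 and shape > 0:
            dist = invgamma(shape, scale=S / 2.0)
            c_lo, c_hi = dist.cdf(lo_sd**2), dist.cdf(hi_sd**2)
            if c_hi - c_lo > 1e-12:
                v = dist.ppf(c_lo + rng.random() * (c_hi - c_lo))
                sigma = float(np.sqrt(np.clip(v, lo_sd**2, hi_sd**2)))
            else:
                sigma = lo_sd if dist.cdf(lo_sd**2) > 0.5 else hi_sd
        else:
            sigma = lo_sd

        if not adapting and (it - mcmc.burn_in) % mcmc.thin == 0 and kept < mcmc.retained_per_chain:
            beta_out[kept] = beta
            sigma_out[kept] = sigma
            u_sum += u
            if u_out is not None:
                u_out[kept] = u
            kept += 1

    return (
        beta_out,
        sigma_out,
        u_sum / max(kept, 1),
        acc_beta / n_iter,
        acc_u / max(n_u_tries, 1),
        u_out,
    )


def fit_log_binomial(
    design: AssocDesign,
    priors: PriorSpec | None = None,
    mcmc: MCMCSettings | None = None,
) -> AssocFit:
    """Sample the posterior of the log-binomial mixed model.

    Runs ``mcmc.chains`` independent seeded chains; flags (without raising)
    non-convergence when any split R-hat exceeds the configured threshold.
    """
    if priors is None:
        priors = PriorSpec()
    if mcmc is None:
        mcmc = MCMCSettings()
    priors.validate()
    if np.linalg.matrix_rank(design.X) < design.X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    seeds = np.random.SeedSequence([mcmc.seed, 17]).spawn(mcmc.chains)
    betas, sigmas, u_means, u_all = [], [], [], []
    acc_b = acc_u = 0.0
    for ss in seeds:
        b, s, um, ab, au, uo = _run_chain(
            design, priors, mcmc, int(ss.generate_state(1, dtype=np.uint32)[0])
        )
        betas.append(b)
        sigmas.append(s)
        u_means.append(um)
        u_all.append(uo)
        acc_b += ab / mcmc.chains
        acc_u += au / mcmc.chains

    beta_draws = np.stack(betas)  # (chains, n, p)
    sigma_draws = np.stack(sigmas)
    rhat = {
        name: _split_rhat(beta_draws[:, :, k])
        for k, name in enumerate(design.columns)
    }
    rhat["sigma_u"] = _split_rhat(sigma_draws)
    converged = all(
        (np.isnan(v) or v < mcmc.rhat_threshold) for v in rhat.values()
    )
    if not converged:
        warnings.warn(
            "MCMC convergence not reached (split R-hat above threshold): "
            + ", ".join(f"{k}={v:.3f}" for k, v in rhat.items() if v >= mcmc.rhat_threshold)
        )
    return AssocFit(
        outcome=design.outcome,
        columns=design.columns,
        beta_draws=beta_draws,
        sigma_draws=sigma_draws,
        u_mean=np.mean(u_means, axis=0),
        study_ids=design.study_ids,
        rhat=rhat,
        converged=converged,
        accept_rates={"beta": acc_b, "u": acc_u},
        u_draws=np.stack(u_all) if mcmc.store_u else None,
    )


def summarize_pr(fit: AssocFit) -> pd.DataFrame:
    """Reporting-style PR summary table.

    Per covariate: posterior mean of exp(beta), 95% credible interval as the
    2.5th and 97.5th percentiles of the exp(beta) draws, and the posterior
    probability that a PR with posterior mean above 1 is below 1 (and vice
    versa for PRs below 1).
    """
    flat = fit.flat_beta()
    rows = []
    for k, name in enumerate(fit.columns):
        pr = np.exp(flat[:, k])
        mean = float(pr.mean())
        lo, hi = np.percentile(pr, [2.5, 97.5])
        if mean > 1.0:
            post_p = float(np.mean(pr < 1.0))
        else:
            post_p = float(np.mean(pr > 1.0))
        rows.append(
            {
                "covariate": name,
                "pr": mean,
                "cri_low": float(lo),
                "cri_high": float(hi),
                "posterior_probability": post_p,
                "rhat": fit.rhat.get(name, np.nan),
            }
        )
    return pd.DataFrame(rows)
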