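"""Model validation battery for the integrated abundance model.

Covers the six diagnostic routes used to establish trust in the fitted
effect sizes: simulation-based parameter recovery, Bayesian checks
(Gelman-Rubin convergence; null-vs-covariate residual-variance
comparison), leave-one-study-area-out cross-validation, single
citizen-source refits, prior-width sensitivity for the regression
coefficients, and a quasi-Poisson GLM screen with classical significance
tests.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from catiam.model import (
    McmcConfig,
    ModelConfig,
    PosteriorDraws,
    fit_iam,
    null_config,
    summarize,
)
from catiam.preprocessing import SiteData

logger = logging.getLogger(__name__)


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor R-hat for one scalar parameter.

    ``chains`` has shape (n_chains, n_draws).  Uses the classic
    between/within-chain variance form: with chain-mean variance B/n and
    mean within-chain variance W, the pooled posterior-variance estimate
    is ((n-1)/n) W + B/n and R-hat its square root ratio to W.  Two
    identical chains therefore give sqrt((n-1)/n); values below 1.1 are
    read as convergence.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a (n_chains >= 2, n_draws) array")
    m, n = arr.shape
    if n < 10:
        raise ValueError("need at least 10 draws per chain")
    chain_means = arr.mean(axis=1)
    B = n * chain_means.var(ddof=1)
    W = arr.var(axis=1, ddof=1).mean()
    if W == 0:
        return np.inf if B > 0 else 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def effect_probability(draws: np.ndarray, direction: str) -> float:
    """Posterior probability that an effect has the stated sign.

    ``direction`` is ``"positive"`` (P(beta > 0)) or ``"negative"``
    (P(beta < 0)); the fraction of draws with that sign.
    """
    arr = np.asarray(draws, dtype=float).reshape(-1)
    if direction == "positive":
        return float(np.mean(arr > 0))
    if direction == "negative":
        return float(np.mean(arr < 0))
    raise ValueError(f"direction must be 'positive' or 'negative', got {direction!r}")


def variance_explained(
    null_sigma_draws: np.ndarray,
    covariate_sigma_draws: np.ndarray,
    functional: str = "mean",
) -> float:
    """Proportion of site-level log-abundance variance explained by covariates.

    The proportional reduction in the residual site-specific variance
    sigma^2 between the covariate-free model and the covariate model:
    ``1 - E[sigma^2_cov] / E[sigma^2_null]`` (posterior means by default;
    ``functional="median"`` uses posterior medians).  Negative values are
    returned as-is.
    """
    f = {"mean": np.mean, "median": np.median}.get(functional)
    if f is None:
        raise ValueError(f"unknown functional {functional!r}")
    v_null = float(f(np.asarray(null_sigma_draws, dtype=float).reshape(-1) ** 2))
    v_cov = float(f(np.asarray(covariate_sigma_draws, dtype=float).reshape(-1) ** 2))
    if v_null <= 0:
        raise ValueError("null-model residual variance must be positive")
    return 1.0 - v_cov / v_null


def _beta_rows(draws: PosteriorDraws, label: dict) -> list[dict]:
    rows = []
    for name in draws.covariate_names:
        mean, lo, hi = summarize(draws, f"beta_{name}")
        rows.append(
            {
                **label,
                "parameter": f"beta_{name}",
                "mean": mean,
                "lower95": lo,
                "upper95": hi,
                "converged": draws.converged,
            }
        )
    return rows


def crossvalidate_by_area(
    sites: Sequence[SiteData],
    model_config: ModelConfig,
    mcmc_config: McmcConfig,
    full_draws: PosteriorDraws | None = None,
) -> pd.DataFrame:
    """Leave-one-study-area-out cross-validation of the effect sizes.

    Refits the model once per study area with all of that area's sites
    withheld and summarizes the regression coefficients per fold.  If the
    full-data draws are supplied, each fold is flagged for overlap of its
    95% CRI with the full-data one.
    """
    areas = sorted({s.study_area for s in sites})
    if len(areas) < 2:
        raise ValueError("need at least 2 distinct study areas")
    full_cri = {}
    if full_draws is not None:
        for name in model_config.covariate_names:
            _, lo, hi = summarize(full_draws, f"beta_{name}")
            full_cri[name] = (lo, hi)

    rows: list[dict] = []
    for fold, area in enumerate(areas):
        keep = [s for s in sites if s.study_area != area]
        if not keep:
            raise ValueError(f"study area {area!r} contains all sites")
        mcmc = replace(mcmc_config, seed=mcmc_config.seed + 1000 + fold)
        draws = fit_iam(keep, model_config, mcmc)
        for row in _beta_rows(draws, {"fold": fold, "held_out_area": area, "n_sites": len(keep)}):
            name = row["parameter"].removeprefix("beta_")
            if name in full_cri:
                lo, hi = full_cri[name]
                row["overlaps_full"] = row["lower95"] <= hi and row["upper95"] >= lo
            rows.append(row)
    return pd.DataFrame(rows)


def single_source_refits(
    sites: Sequence[SiteData],
    model_config: ModelConfig,
    mcmc_config: McmcConfig,
) -> pd.DataFrame:
    """Refit with only one citizen-science stream at a time.

    The "survey" variant drops all report replicates (and the report
    observation parameters), the "report" variant the survey replicates;
    expert data are kept unchanged.  Only sites retaining at least one
    replicate of the kept source are used.  Reports per-variant effect
    summaries and the retained sites' covariate ranges.
    """
    rows: list[dict] = []
    for variant, kept_attr in (("survey", "y"), ("report", "u")):
        retained = []
        for s in sites:
            if getattr(s, kept_attr).size == 0:
                continue
            retained.append(
                SiteData(
                    site_id=s.site_id,
                    y=s.y if variant == "survey" else np.empty(0),
                    u=s.u if variant == "report" else np.empty(0),
                    w=s.w,
                    expert_occupancy=s.expert_occupancy,
                    covariates=dict(s.covariates),
                    study_area=s.study_area,
                )
            )
        if len(retained) < 10:
            logger.warning("%s-only refit retains only %d sites", variant, len(retained))
        mcmc = replace(mcmc_config, seed=mcmc_config.seed + (31 if variant == "survey" else 57))
        draws = fit_iam(retained, model_config, mcmc)
        label = {"variant": variant, "n_sites": len(retained)}
        for name in model_config.covariate_names:
            vals = [s.covariates[name] for s in retained]
            label[f"{name}_min"], label[f"{name}_max"] = float(min(vals)), float(max(vals))
        rows.extend(_beta_rows(draws, label))
    return pd.DataFrame(rows)


def prior_sensitivity(
    sites: Sequence[SiteData],
    model_config: ModelConfig,
    mcmc_config: McmcConfig,
    widths: Sequence[float] = (0.5, 5.0, 10.0),
) -> pd.DataFrame:
    """Refit under different uniform prior half-widths for the coefficients.

    The default widths bracket the working prior U(-5,5) with a narrower
    U(-0.5,0.5) and a wider U(-10,10).  A posterior mass piling within 5%
    of a prior bound is flagged as truncated.
    """
    rows: list[dict] = []
    for k, width in enumerate(widths):
        cfg = replace(model_config, beta_bound=float(width))
        mcmc = replace(mcmc_config, seed=mcmc_config.seed + 2000 + k)
        draws = fit_iam(sites, cfg, mcmc)
        for row in _beta_rows(draws, {"prior_width": float(width)}):
            margin = 0.05 * 2 * width
            row["at_bound"] = (
                row["upper95"] > width - margin or row["lower95"] < -width + margin
            )
            if row["at_bound"]:
                logger.warning(
                    "posterior of %s piles at the U(-%g, %g) prior bound",
                    row["parameter"], width, width,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def glm_screen(
    site_abundance_estimates: np.ndarray,
    covariate_table: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Quasi-Poisson GLM screen of candidate covariates.

    Regresses per-site abundance estimates (posterior means from the
    null IAM) on the covariates with a log link; standard errors are
    scaled by the Pearson dispersion estimate and tested two-sided.
    Returns one row per term with coefficient, SE, t, p, dispersion and
    a significance flag at ``alpha``.
    """
    y = np.asarray(site_abundance_estimates, dtype=float)
    X = sm.add_constant(covariate_table.astype(float), has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(scale="X2")  # quasi-Poisson: Pearson chi^2 dispersion
    frame = pd.DataFrame(
        {
            "term": res.params.index,
            "coef": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "t": res.tvalues.to_numpy(),
            "p": res.pvalues.to_numpy(),
        }
    )
    frame["dispersion"] = float(res.scale)
    frame["significant"] = frame["p"] < alpha
    return frame


def simulation_recovery(
    truth_config,
    n_reps: int = 20,
    mcmc_config: McmcConfig | None = None,
    model_config: ModelConfig | None = None,
    parameters: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate-and-refit calibration of the sampler.

    Generates ``n_reps`` datasets from ``truth_config`` (seeds derived
    from its seed), refits each, and reports per parameter the coverage
    of the 95% credible intervals, the mean signed bias of the posterior
    means, and the count of replicates flagged as non-converged (reported,
    never dropped).  Coverage comes with a binomial standard error.
    """
    from catiam.synthetic import simulate_sites, with_seed

    if n_reps < 2:
        raise ValueError("need n_reps >= 2")
    mcmc = mcmc_config or McmcConfig.reduced()
    cfg = model_config or ModelConfig(covariate_names=truth_config.covariate_names)

    truth_values = {
        "mu": truth_config.mu,
        "sigma": truth_config.sigma,
        "omega": truth_config.omega,
        "p_survey": truth_config.p_survey,
        "p_report": truth_config.p_report,
        "m_survey": truth_config.m_survey,
        "m_report": truth_config.m_report,
    }
    for j, name in enumerate(truth_config.covariate_names):
        if name in cfg.covariate_names:
            truth_values[f"beta_{name}"] = truth_config.beta[j]
    names = list(parameters) if parameters else list(truth_values)

    records = {k: {"covered": 0, "bias": [], "nonconverged": 0} for k in names}
    for rep in range(n_reps):
        data = simulate_sites(with_seed(truth_config, truth_config.seed + 7919 * (rep + 1)))
        draws = fit_iam(data.sites, cfg, replace(mcmc, seed=mcmc.seed + rep))
        for k in names:
            mean, lo, hi = summarize(draws, k)
            rec = records[k]
            rec["covered"] += int(lo <= truth_values[k] <= hi)
            rec["bias"].append(mean - truth_values[k])
            rec["nonconverged"] += int(not draws.converged)

    rows = []
    for k in names:
        rec = records[k]
        cov = rec["covered"] / n_reps
        rows.append(
            {
                "parameter": k,
                "truth": truth_values[k],
                "coverage95": cov,
                "coverage_se": float(np.sqrt(cov * (1 - cov) / n_reps)),
                "mean_bias": float(np.mean(rec["bias"])),
                "n_reps": n_reps,
                "n_nonconverged": rec["nonconverged"],
            }
        )
    return pd.DataFrame(rows)
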