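"""Project posterior effect sizes onto small-area geographies.

For each small area (an LSOA in England & Wales, SOA in Northern
Ireland, data zone in Scotland) and each retained posterior draw d the
predicted unowned cat abundance is

    exp(mu_d + beta_imd,d * IMD + beta_pd,d * min(PD_std, cap)) * SP

where IMD is the area's deprivation measure on the scale the model was
fitted on, PD_std its human population density standardized against the
*fitting* data's mean/SD, and SP = land_area / reference_site_area scales
a site-level abundance to the geography.  Population density is truncated
at the largest density seen during fitting, a conservative guard against
extrapolating the positive density effect into unobserved regimes (dense
London boroughs in particular).  Totals are formed draw-wise and only
then summarized, so aggregate credible intervals propagate the full
posterior dependence between areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from catiam.model import PosteriorDraws
from catiam.preprocessing import Standardizer

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictionConfig:
    """Settings of the abundance projection.

    ``density_cap`` is in raw people per km^2 (study upper limit 15,129)
    and is standardized internally with the fitting standardizer.
    ``reference_site_area`` is the km^2 of one model site; the default
    0.2 km^2 is the 20 ha assumed-maximum home range that defined the
    500 m clusters.  ``include_lognormal_correction`` optionally adds the
    residual-variance mean correction exp(sigma^2/2); the projection
    formula is otherwise evaluated literally (no residual or occupancy
    term), default off.
    """

    density_cap: float = 15_129.0
    reference_site_area: float = 0.2
    include_lognormal_correction: bool = False
    imd_scale: str = "decile"

    def __post_init__(self) -> None:
        if self.density_cap <= 0 or self.reference_site_area <= 0:
            raise ValueError("density_cap and reference_site_area must be positive")
        if self.imd_scale not in ("decile", "quintile"):
            raise ValueError("imd_scale must be 'decile' or 'quintile'")


@dataclass
class PredictionResult:
    """Per-area and aggregate posterior abundance/density summaries."""

    areas: pd.DataFrame  # area_id, country, mean, lower95, upper95, density_mean, land_area_km2
    aggregates: pd.DataFrame  # group, mean, lower95, upper95
    draw_totals: dict[str, np.ndarray]  # per-group per-draw totals


def _extract_effect_draws(
    draws: PosteriorDraws | Mapping[str, np.ndarray], config: PredictionConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None]:
    if isinstance(draws, PosteriorDraws):
        imd_name = next((n for n in draws.covariate_names if n.startswith("imd")), None)
        pd_name = next((n for n in draws.covariate_names if "dens" in n or n == "popdens"), None)
        if imd_name is None or pd_name is None:
            raise ValueError(
                "posterior draws must carry an IMD and a population-density effect"
            )
        mu = draws.stacked("mu")
        b_imd = draws.stacked(f"beta_{imd_name}")
        b_pd = draws.stacked(f"beta_{pd_name}")
        sigma = draws.stacked("sigma")
    else:
        mu = np.asarray(draws["mu"], dtype=float).reshape(-1)
        b_imd = np.asarray(draws["beta_imd"], dtype=float).reshape(-1)
        b_pd = np.asarray(draws["beta_popdens"], dtype=float).reshape(-1)
        sigma = np.asarray(draws["sigma"], dtype=float).reshape(-1) if "sigma" in draws else None
    return mu, b_imd, b_pd, sigma


def predict_areas(
    draws: PosteriorDraws | Mapping[str, np.ndarray],
    areas: pd.DataFrame,
    config: PredictionConfig,
    density_standardizer: Standardizer,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-draw predicted abundance for every area.

    ``areas`` needs columns ``area_id``, ``imd_<scale>``, ``pop_density``
    and ``land_area_km2`` (``country`` optional).  Areas with missing
    covariates are excluded with a log message.  Returns an
    ``(n_draws, n_areas)`` array of strictly positive abundances and the
    (possibly filtered) area table.
    """
    imd_col = f"imd_{config.imd_scale}"
    for col in (imd_col, "pop_density", "land_area_km2"):
        if col not in areas.columns:
            raise ValueError(f"areas table lacks column {col!r}")
    ok = areas[[imd_col, "pop_density", "land_area_km2"]].notna().all(axis=1)
    if not ok.all():
        logger.info("excluding %d areas with missing covariates", int((~ok).sum()))
    areas = areas.loc[ok].reset_index(drop=True)

    mu, b_imd, b_pd, sigma = _extract_effect_draws(draws, config)
    cap_std = float(density_standardizer.transform([config.density_cap])[0])
    pd_std = np.minimum(
        density_standardizer.transform(areas["pop_density"].to_numpy()), cap_std
    )
    imd = areas[imd_col].to_numpy(dtype=float)
    sp = areas["land_area_km2"].to_numpy(dtype=float) / config.reference_site_area

    log_pred = (
        mu[:, None] + np.outer(b_imd, imd) + np.outer(b_pd, pd_std)
    )
    if config.include_lognormal_correction:
        if sigma is None:
            raise ValueError("lognormal correction requested but sigma draws absent")
        log_pred = log_pred + (sigma[:, None] ** 2) / 2.0
    return np.exp(log_pred) * sp[None, :], areas


def _summary(draws_1d: np.ndarray) -> tuple[float, float, float]:
    lo, hi = np.quantile(draws_1d, [0.025, 0.975])
    return float(draws_1d.mean()), float(lo), float(hi)


def aggregate(
    per_area_draws: np.ndarray,
    areas: pd.DataFrame,
    group_col: str | None = "country",
    total_label: str = "UK",
) -> PredictionResult:
    """Summarize per-area draws and draw-wise group/overall totals.

    Group totals are formed per draw and only then summarized, so the
    per-draw total equals the sum of per-draw area values exactly and
    interval widths reflect posterior dependence.
    """
    draws = np.asarray(per_area_draws, dtype=float)
    if draws.ndim != 2 or draws.shape[1] != len(areas):
        raise ValueError("per_area_draws must be (n_draws, n_areas) matching the table")

    area_rows = []
    means, los, his = draws.mean(axis=0), *np.quantile(draws, [0.025, 0.975], axis=0)
    for k, (_, row) in enumerate(areas.iterrows()):
        area_rows.append(
            {
                "area_id": row["area_id"],
                "country": row.get("country", total_label),
                "mean": means[k],
                "lower95": los[k],
                "upper95": his[k],
                "land_area_km2": row["land_area_km2"],
                "density_mean": means[k] / row["land_area_km2"],
            }
        )
    area_df = pd.DataFrame(area_rows)

    draw_totals: dict[str, np.ndarray] = {}
    agg_rows = []
    if group_col and group_col in areas.columns:
        for grp in sorted(areas[group_col].astype(str).unique()):
            mask = (areas[group_col].astype(str) == grp).to_numpy()
            tot = draws[:, mask].sum(axis=1)
            draw_totals[grp] = tot
            m, lo, hi = _summary(tot)
            agg_rows.append({"group": grp, "mean": m, "lower95": lo, "upper95": hi,
                             "land_area_km2": float(areas.loc[mask, "land_area_km2"].sum())})
    overall = draws.sum(axis=1)
    draw_totals[total_label] = overall
    m, lo, hi = _summary(overall)
    agg_rows.append({"group": total_label, "mean": m, "lower95": lo, "upper95": hi,
                     "land_area_km2": float(areas["land_area_km2"].sum())})
    return PredictionResult(areas=area_df, aggregates=pd.DataFrame(agg_rows), draw_totals=draw_totals)


def density_summary(result: PredictionResult) -> tuple[pd.DataFrame, float]:
    """Per-area mean densities (cats per km^2) and their median over areas."""
    df = result.areas[["area_id", "country", "density_mean", "land_area_km2"]].copy()
    return df, float(df["density_mean"].median())


def prediction_validation(
    predicted: pd.DataFrame,
    reference: pd.DataFrame,
) -> tuple[float, float, float]:
    """Compare projected densities against reference per-site estimates.

    Both frames are keyed by ``area_id``; ``predicted`` needs a ``mean``
    column and ``reference`` columns ``mean``, ``lower95``, ``upper95``.
    Returns (overlap fraction: share of predictions inside the reference
    95% CRIs; Spearman correlation of the means; its p-value).
    """
    merged = predicted.merge(reference, on="area_id", suffixes=("_pred", "_ref"))
    if merged.empty:
        raise ValueError("no matched area identifiers")
    inside = (
        (merged["mean_pred"] >= merged["lower95"]) & (merged["mean_pred"] <= merged["upper95"])
    )
    rho, pval = stats.spearmanr(merged["mean_pred"], merged["mean_ref"])
    return float(inside.mean()), float(rho), float(pval)


def summarize_geography(areas: pd.DataFrame) -> pd.DataFrame:
    """Counts and land-area totals per country, plus an overall row."""
    g = (
        areas.groupby("country", as_index=False)
        .agg(n_areas=("area_id", "size"), land_area_km2=("land_area_km2", "sum"))
        .sort_values("country", ignore_index=True)
    )
    total = pd.DataFrame(
        {"country": ["total"], "n_areas": [len(areas)], "land_area_km2": [areas["land_area_km2"].sum()]}
    )
    return pd.concat([g, total], ignore_index=True)


def fraction_above(values: Sequence[float], cap: float) -> float:
    """Fraction of values strictly above a cap (e.g. share of areas whose
    density exceeds the fitted range)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values")
    return float(np.mean(arr > cap))
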