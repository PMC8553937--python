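"""Synthetic datasets with the statistical structure the abundance model assumes.

The generator emulates the study design: 162 sighting-defined sites spread
over five urban study areas, replicated door-to-door survey counts and
resident report counts at every site, and accurate expert counts at about
64% of sites.  Site abundance follows a zero-inflated Poisson-lognormal:
occupancy z_i ~ Bernoulli(omega), log-intensity
log lambda_i = mu + sum_j beta_j x_ij + eps_i with eps_i ~ N(0, sigma^2),
and N_i = z_i * lambda_i.  Citizen replicate counts are
Poisson(N_i * p + m): detection probability p thins the true abundance and
the misidentification rate m adds owned cats wrongly reported as unowned.
Expert counts are Poisson(N_i) with no observation bias.

Random streams are split per data type (covariates / latent states /
survey / report / expert) so e.g. changing replicate-count ranges does not
perturb the latent abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from catiam.preprocessing import SiteData

#: Default covariate names: English Index of Multiple Deprivation decile
#: (1 = most deprived, entering the model unstandardized on its 1-10
#: scale) and standardized human population density.
DEFAULT_COVARIATES = ("imd", "popdens")


@dataclass(frozen=True)
class TruthConfig:
    """Generating parameters for a synthetic study.

    Defaults mirror the study conditions: 162 sites in 5 urban areas,
    survey detection ~0.179 with ~0.72 misidentified owned cats per
    replicate, report detection ~0.245 with ~1.8, expert coverage 64%,
    effect sizes -0.32 (IMD decile) and 0.31 (standardized density).
    mu and sigma are set so the median occupied site holds ~2.6 cats on a
    0.2 km^2 site and the covariates explain ~37% of the site-level
    log-abundance variance.
    """

    n_sites: int = 162
    n_study_areas: int = 5
    mu: float = 2.7
    beta: tuple[float, ...] = (-0.32, 0.31)
    sigma: float = 1.27
    omega: float = 0.8
    p_survey: float = 0.179
    p_report: float = 0.245
    m_survey: float = 0.72
    m_report: float = 1.8
    expert_coverage: float = 0.64
    replicates_survey: tuple[int, int] = (5, 30)
    replicates_report: tuple[int, int] = (1, 10)
    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES
    imd_density_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_study_areas < 1:
            raise ValueError("n_sites and n_study_areas must be positive")
        for name in ("omega", "p_survey", "p_report", "expert_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.sigma < 3.0:
            raise ValueError("sigma outside [0, 3)")
        for name in ("m_survey", "m_report"):
            v = getattr(self, name)
            if not 0.0 <= v < 5.0:
                raise ValueError(f"{name}={v} outside [0, 5)")
        if len(self.beta) != len(self.covariate_names):
            raise ValueError("beta length must equal covariate count")
        for lo, hi in (self.replicates_survey, self.replicates_report):
            if lo < 1 or hi < lo:
                raise ValueError("replicate ranges must be positive and ordered")


@dataclass
class SyntheticDataset:
    """A simulated study: per-site data plus the realized latent truth."""

    sites: list[SiteData]
    truth: TruthConfig
    lam: np.ndarray  # realized site intensities lambda_i
    z: np.ndarray  # realized occupancy indicators
    covariates: pd.DataFrame  # one row per site
    sightings: pd.DataFrame | None = None  # optional raw-point form

    @property
    def n(self) -> np.ndarray:
        """True site abundances N_i = z_i * lambda_i."""
        return self.z * self.lam


def _draw_covariates(cfg: TruthConfig, rng: np.random.Generator) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    rho = cfg.imd_density_correlation
    base = rng.standard_normal(cfg.n_sites)
    for name in cfg.covariate_names:
        if name == "imd":
            cols[name] = rng.integers(1, 11, size=cfg.n_sites).astype(float)
        elif name == "popdens":
            if rho != 0.0 and "imd" in cols:
                # IMD decile 1 = most deprived; deprived areas tend denser,
                # so couple density to the *negated* standardized decile
                imd_std = (cols["imd"] - cols["imd"].mean()) / max(cols["imd"].std(), 1e-12)
                cols[name] = -rho * imd_std + np.sqrt(1 - rho**2) * base
            else:
                cols[name] = base
        else:
            cols[name] = rng.standard_normal(cfg.n_sites)
    df = pd.DataFrame(cols)
    df["study_area"] = [f"area_{i % cfg.n_study_areas + 1}" for i in range(cfg.n_sites)]
    return df


def simulate_sites(
    config: TruthConfig, covariate_table: pd.DataFrame | None = None
) -> SyntheticDataset:
    """Simulate a full replicated-count dataset under the abundance model.

    Deterministic for a fixed ``config.seed``.  If ``covariate_table`` is
    given (one row per site with the configured covariate columns and
    optionally ``study_area``) it is used instead of drawing covariates.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_cov, rng_latent, rng_survey, rng_report, rng_expert = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    if covariate_table is not None:
        cov = covariate_table.reset_index(drop=True).copy()
        if len(cov) != cfg.n_sites:
            raise ValueError("covariate_table must have one row per site")
        if "study_area" not in cov.columns:
            cov["study_area"] = [
                f"area_{i % cfg.n_study_areas + 1}" for i in range(cfg.n_sites)
            ]
    else:
        cov = _draw_covariates(cfg, rng_cov)

    X = cov[list(cfg.covariate_names)].to_numpy(dtype=float)
    eps = rng_latent.normal(0.0, cfg.sigma, size=cfg.n_sites) if cfg.sigma > 0 else np.zeros(cfg.n_sites)
    log_lam = cfg.mu + X @ np.asarray(cfg.beta, dtype=float) + eps
    if np.any(np.abs(log_lam) > 50):
        bad = int(np.argmax(np.abs(log_lam) > 50))
        raise ValueError(
            f"non-finite linear predictor at site {bad}: |log lambda| = "
            f"{abs(log_lam[bad]):.1f} > 50; check mu/beta/covariate scales"
        )
    lam = np.exp(log_lam)
    z = (rng_latent.random(cfg.n_sites) < cfg.omega).astype(int) if cfg.omega < 1 else np.ones(cfg.n_sites, dtype=int)
    n_true = z * lam

    n_survey = rng_survey.integers(
        cfg.replicates_survey[0], cfg.replicates_survey[1] + 1, size=cfg.n_sites
    )
    n_report = rng_report.integers(
        cfg.replicates_report[0], cfg.replicates_report[1] + 1, size=cfg.n_sites
    )
    expert_mask = rng_expert.random(cfg.n_sites) < cfg.expert_coverage

    sites: list[SiteData] = []
    for i in range(cfg.n_sites):
        y = rng_survey.poisson(n_true[i] * cfg.p_survey + cfg.m_survey, size=n_survey[i])
        u = rng_report.poisson(n_true[i] * cfg.p_report + cfg.m_report, size=n_report[i])
        w = int(rng_expert.poisson(n_true[i])) if expert_mask[i] else None
        sites.append(
            SiteData(
                site_id=i,
                y=y.astype(float),
                u=u.astype(float),
                w=w,
                expert_occupancy="unknown" if w is None else ("present" if w > 0 else "absent"),
                covariates={k: float(X[i, j]) for j, k in enumerate(cfg.covariate_names)},
                study_area=str(cov["study_area"].iloc[i]),
            )
        )
    return SyntheticDataset(sites=sites, truth=cfg, lam=lam, z=z, covariates=cov)


def scatter_sightings(
    dataset: SyntheticDataset, seed: int = 0, site_spacing_m: float = 2_000.0, jitter_m: float = 200.0
) -> pd.DataFrame:
    """Lay the dataset's records out as raw geo-referenced points.

    Sites are placed on a square grid ``site_spacing_m`` apart (well beyond
    the 500 m clustering radius) and each record jittered within
    ``jitter_m`` of its site centre, so clustering the emitted points
    recovers the site structure exactly.  Returns a sightings table in the
    standard format (record_id, observer_type, x, y, crs, raw_value,
    study_area).
    """
    if jitter_m * 2 >= 500.0:
        raise ValueError("jitter must keep within-site distances under the 500 m radius")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(len(dataset.sites))))
    rows = []
    rid = 0
    for i, site in enumerate(dataset.sites):
        cx = (i % side) * site_spacing_m
        cy = (i // side) * site_spacing_m
        records: list[tuple[str, float]] = [("survey", v) for v in site.y]
        records += [("report", v) for v in site.u]
        if site.w is not None:
            records.append(("expert", float(site.w)))
        for obs, val in records:
            dx, dy = rng.uniform(-jitter_m / 2, jitter_m / 2, size=2)
            rows.append(
                {
                    "record_id": rid,
                    "observer_type": obs,
                    "x": cx + dx,
                    "y": cy + dy,
                    "crs": "metres",
                    "raw_value": val,
                    "study_area": site.study_area,
                    # area-level covariates travel with every record so the
                    # clustered file is self-contained for fitting
                    **{f"cov_{k}": v for k, v in sorted(site.covariates.items())},
                }
            )
            rid += 1
    return pd.DataFrame(rows)


def make_area_table(
    n_areas: int,
    country_mix: dict[str, float] | None = None,
    seed: int = 0,
    mean_density: float = 5303.0,
    mean_land_area_km2: float = 0.904,
    imd_scale: str = "decile",
) -> pd.DataFrame:
    """Generate a small-area statistics table (stand-in for census geographies).

    Each row is one small-area geography with a country label, a
    deprivation measure (decile 1-10 or UK-adjusted quintile 1-5), a human
    population density (lognormal, mean ``mean_density`` people per km^2,
    matching urban English small areas) and a land area in km^2 (lognormal,
    default mean chosen so ~34k areas total ~30.7k km^2 of urban land).
    Reproducible for a fixed seed.
    """
    if n_areas < 1:
        raise ValueError("n_areas must be >= 1")
    if imd_scale not in ("decile", "quintile"):
        raise ValueError("imd_scale must be 'decile' or 'quintile'")
    # default mix follows the UK urban small-area counts: 28,549 LSOAs
    # (England & Wales, roughly 27,246 / 1,303), 4,909 Scottish data
    # zones, 530 Northern Irish SOAs
    mix = country_mix or {
        "England": 27_246 / 33_988,
        "Wales": 1_303 / 33_988,
        "Scotland": 4_909 / 33_988,
        "N. Ireland": 530 / 33_988,
    }
    countries = list(mix)
    probs = np.asarray([mix[c] for c in countries], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    country = rng.choice(countries, size=n_areas, p=probs)

    top = 10 if imd_scale == "decile" else 5
    imd = rng.integers(1, top + 1, size=n_areas)
    # lognormal with ~1 log-unit spread; scaled to the requested mean
    dens_sigma = 0.9
    density = rng.lognormal(np.log(mean_density) - dens_sigma**2 / 2, dens_sigma, size=n_areas)
    area_sigma = 0.6
    land = rng.lognormal(np.log(mean_land_area_km2) - area_sigma**2 / 2, area_sigma, size=n_areas)
    df = pd.DataFrame(
        {
            "area_id": [f"A{i:06d}" for i in range(n_areas)],
            "country": country,
            f"imd_{imd_scale}": imd,
            "pop_density": density,
            "land_area_km2": land,
            "urban": True,
        }
    )
    return df


def with_seed(config: TruthConfig, seed: int) -> TruthConfig:
    """Copy of ``config`` with a different random seed."""
    return replace(config, seed=seed)
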