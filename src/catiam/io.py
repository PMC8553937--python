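"""CSV/YAML input and output with provenance headers.

All tabular artifacts are UTF-8 comma-separated CSV with "." decimals.
Files written here begin with ``#``-prefixed comment lines carrying the
package version, the seed and a hash of the generating configuration, so
every output is traceable to its run; the readers skip such lines.
Errors cite 1-based data row numbers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from catiam.preprocessing import OBSERVER_TYPES, SURVEY_CHOICE_VALUES, SiteData, _normalize_choice

SIGHTING_COLUMNS = ["record_id", "observer_type", "x", "y", "crs", "raw_value", "study_area"]


def config_hash(config: Any) -> str:
    """Stable short hash of a configuration (dataclass or mapping)."""
    obj = asdict(config) if is_dataclass(config) else dict(config)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: Any = None,
    overwrite: bool = False,
) -> Path:
    """Write a CSV with a provenance comment header."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    path.parent.mkdir(parents=True, exist_ok=True)
    from catiam import __version__

    lines = [f"# catiam {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_sightings(path: str | Path) -> pd.DataFrame:
    """Read and validate a sightings CSV.

    Columns: record_id, observer_type (survey|report|expert), x, y, crs
    (metres|wgs84), raw_value (count, or a survey category string),
    study_area.  Rejections cite the offending 1-based data row.
    """
    df = read_table(path)
    missing = [c for c in SIGHTING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for i, row in df.iterrows():
        rowno = i + 1
        if row["observer_type"] not in OBSERVER_TYPES:
            raise ValueError(
                f"{path} row {rowno}: unknown observer_type {row['observer_type']!r}"
            )
        for coord in ("x", "y"):
            try:
                v = float(row[coord])
            except (TypeError, ValueError):
                v = np.nan
            if not np.isfinite(v):
                raise ValueError(f"{path} row {rowno}: unparseable coordinate {row[coord]!r}")
        raw = row["raw_value"]
        if row["observer_type"] == "survey":
            try:
                val = float(raw)
            except (TypeError, ValueError):
                if _normalize_choice(raw) not in SURVEY_CHOICE_VALUES:
                    raise ValueError(f"{path} row {rowno}: bad survey category {raw!r}")
                continue
            if val < 0:
                raise ValueError(f"{path} row {rowno}: negative count {raw!r}")
        else:
            try:
                val = float(raw)
            except (TypeError, ValueError):
                raise ValueError(f"{path} row {rowno}: unparseable count {raw!r}")
            if val < 0:
                raise ValueError(f"{path} row {rowno}: negative count {raw!r}")
    return df


def read_areas(path: str | Path) -> tuple[pd.DataFrame, str]:
    """Read a small-area statistics CSV; IMD scale auto-detected from the
    column name (imd_decile or imd_quintile).  Returns (table, scale)."""
    df = read_table(path)
    if "imd_decile" in df.columns:
        scale, top = "decile", 10
    elif "imd_quintile" in df.columns:
        scale, top = "quintile", 5
    else:
        raise ValueError(f"{path}: need an imd_decile or imd_quintile column")
    for col in ("area_id", "pop_density", "land_area_km2"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    imd = df[f"imd_{scale}"]
    bad = df.index[(imd < 1) | (imd > top) | (imd != imd.astype(int))]
    if len(bad):
        raise ValueError(
            f"{path} row {bad[0] + 1}: imd_{scale} value {imd[bad[0]]!r} outside 1-{top}"
        )
    if (df["land_area_km2"] <= 0).any():
        rowno = int(df.index[df["land_area_km2"] <= 0][0]) + 1
        raise ValueError(f"{path} row {rowno}: non-positive land area")
    if (df["pop_density"] < 0).any():
        rowno = int(df.index[df["pop_density"] < 0][0]) + 1
        raise ValueError(f"{path} row {rowno}: negative population density")
    return df, scale


def sites_to_frames(sites: list[SiteData]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize sites as (replicates frame, site-summary frame)."""
    rep_rows, sum_rows = [], []
    for s in sites:
        for kind, vals in (("survey", s.y), ("report", s.u)):
            for v in vals:
                rep_rows.append({"site_id": s.site_id, "observer_type": kind, "count": v})
        sum_rows.append(
            {
                "site_id": s.site_id,
                "study_area": s.study_area,
                "n_survey": s.y.size,
                "n_report": s.u.size,
                "expert_count": s.w if s.w is not None else "",
                "expert_occupancy": s.expert_occupancy,
                **{f"cov_{k}": v for k, v in sorted(s.covariates.items())},
            }
        )
    return pd.DataFrame(rep_rows), pd.DataFrame(sum_rows)


def frames_to_sites(replicates: pd.DataFrame, summary: pd.DataFrame) -> list[SiteData]:
    """Inverse of :func:`sites_to_frames`."""
    sites = []
    for _, row in summary.iterrows():
        sid = int(row["site_id"])
        grp = replicates[replicates["site_id"] == sid]
        y = grp.loc[grp["observer_type"] == "survey", "count"].to_numpy(dtype=float)
        u = grp.loc[grp["observer_type"] == "report", "count"].to_numpy(dtype=float)
        w_raw = row.get("expert_count", "")
        w = None if (pd.isna(w_raw) or w_raw == "") else int(float(w_raw))
        covs = {
            k.removeprefix("cov_"): float(v)
            for k, v in row.items()
            if str(k).startswith("cov_")
        }
        sites.append(
            SiteData(
                site_id=sid,
                y=y,
                u=u,
                w=w,
                expert_occupancy=str(row["expert_occupancy"]),
                covariates=covs,
                study_area=str(row.get("study_area", "")),
            )
        )
    return sites


def write_draws(draws, path: str | Path, overwrite: bool = False) -> Path:
    """Posterior scalar draws as tidy CSV (chain, iteration, parameter, value)."""
    return write_table(draws.to_dataframe(), path, seed=draws.seed, overwrite=overwrite)


def read_draws(path: str | Path) -> dict[str, np.ndarray]:
    """Read tidy draws back as parameter -> (n_chains, n_draws) arrays."""
    df = read_table(path)
    out = {}
    for name, grp in df.groupby("parameter"):
        chains = [g["value"].to_numpy() for _, g in grp.groupby("chain")]
        out[str(name)] = np.vstack(chains)
    return out


def load_config(path: str | Path) -> dict:
    """Read a YAML pipeline configuration."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"{path}: expected a mapping at top level")
    return dict(cfg)
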