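"""Turn raw geo-referenced sightings into site-structured replicate counts.

Sites are defined by single-linkage clustering of sighting locations at a
500 m cutoff: the cutoff corresponds to the diameter of a circular 20 ha
home range (the assumed maximum for an urban unowned cat), so records
closer than that plausibly describe the same animals and are kept as
replicate counts of one population unit rather than as separate sites.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_008.8

#: Midpoint encoding of the survey multiple-choice categories.  The open
#: top category "10 or more" is coded 15 (close to the mean of free-text
#: reports that specified ten or more cats).
SURVEY_CHOICE_VALUES: dict[str, float] = {
    "none": 0.0,
    "1-2": 1.5,
    "3-4": 3.5,
    "5-9": 7.0,
    "10 or more": 15.0,
}

OBSERVER_TYPES = ("survey", "report", "expert")


def _normalize_choice(choice: str) -> str:
    # accept en-dash variants and stray whitespace/case
    return str(choice).strip().lower().replace("–", "-").replace("—", "-")


def encode_survey_response(choice: str) -> float:
    """Encode a survey multiple-choice category as a numeric count.

    Ranges map to their central value; "10 or more" maps to 15.
    """
    key = _normalize_choice(choice)
    if key not in SURVEY_CHOICE_VALUES:
        raise ValueError(
            f"unrecognized survey category {choice!r}; expected one of "
            f"{sorted(SURVEY_CHOICE_VALUES)}"
        )
    return SURVEY_CHOICE_VALUES[key]


def circle_diameter_m(area_ha: float) -> float:
    """Diameter in metres of a circle with the given area in hectares.

    Used to translate an assumed maximum home-range area into the
    distance cutoff for clustering (20 ha -> 504.6 m).
    """
    if area_ha <= 0:
        raise ValueError("area must be positive")
    area_m2 = area_ha * 10_000.0
    return 2.0 * math.sqrt(area_m2 / math.pi)


@dataclass
class SiteData:
    """Replicate count data and covariates for one site (500 m cluster)."""

    site_id: int
    y: np.ndarray  # survey replicate counts (may be half-integer midpoints)
    u: np.ndarray  # report replicate counts
    w: int | None = None  # expert consensus count, None if no expert visit
    expert_occupancy: str = "unknown"  # "present" | "absent" | "unknown"
    covariates: dict[str, float] = field(default_factory=dict)
    study_area: str = ""

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.expert_occupancy not in ("present", "absent", "unknown"):
            raise ValueError(f"bad expert_occupancy {self.expert_occupancy!r}")
        if np.any(self.y < 0) or np.any(self.u < 0):
            raise ValueError(f"site {self.site_id}: negative counts")
        if self.w is not None and self.w < 0:
            raise ValueError(f"site {self.site_id}: negative expert count")
        if self.w is not None and self.expert_occupancy == "unknown":
            self.expert_occupancy = "present" if self.w > 0 else "absent"

    @property
    def n_citizen_replicates(self) -> int:
        return self.y.size + self.u.size


def _pairwise_sites_euclidean(xy: np.ndarray, radius_m: float) -> list[tuple[int, int]]:
    tree = cKDTree(xy)
    return sorted(tree.query_pairs(radius_m, output_type="set"))


def _pairwise_sites_haversine(lonlat: np.ndarray, radius_m: float) -> list[tuple[int, int]]:
    from sklearn.neighbors import BallTree

    rad = np.radians(lonlat[:, ::-1])  # BallTree haversine wants (lat, lon)
    tree = BallTree(rad, metric="haversine")
    ind = tree.query_radius(rad, r=radius_m / EARTH_RADIUS_M)
    pairs = {(min(i, j), max(i, j)) for i, nb in enumerate(ind) for j in nb if i != j}
    return sorted(pairs)


def cluster_sightings(records: pd.DataFrame, radius_m: float = 500.0) -> np.ndarray:
    """Assign each sighting record to a site by single-linkage clustering.

    Any two records within ``radius_m`` of each other share a site, with
    membership chained transitively (connected components of the proximity
    graph).  Records must carry ``x``/``y`` coordinates and a ``crs``
    column that is either ``"metres"`` (planar, Euclidean distance) or
    ``"wgs84"`` (lon/lat, haversine distance); mixing the two is rejected.

    Returns an integer site label per record.  Labels are assigned in
    order of each cluster's first member after a lexicographic coordinate
    sort, so the labelling is invariant to the input row order.
    """
    if radius_m < 0:
        raise ValueError("radius_m must be non-negative")
    required = {"x", "y"}
    if not required.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    xy = records[["x", "y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        bad = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0])
        raise ValueError(f"non-finite coordinates at record index {bad}")

    crs_values = set(records["crs"].unique()) if "crs" in records.columns else {"metres"}
    if len(crs_values) > 1:
        raise ValueError(
            f"mixed coordinate reference systems {sorted(crs_values)}; "
            "convert to a single frame first"
        )
    crs = crs_values.pop()
    n = len(xy)
    if n == 0:
        return np.empty(0, dtype=int)
    if radius_m == 0:
        pairs = []
    elif crs == "metres":
        pairs = _pairwise_sites_euclidean(xy, radius_m)
    elif crs == "wgs84":
        logger.info("lon/lat coordinates: clustering with haversine distances")
        pairs = _pairwise_sites_haversine(xy, radius_m)
    else:
        raise ValueError(f"unknown crs {crs!r}; expected 'metres' or 'wgs84'")

    if pairs:
        rows, cols = zip(*pairs)
        graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    else:
        graph = coo_matrix((n, n))
    _, labels = connected_components(graph, directed=False)

    # relabel deterministically: component order = lexicographic order of the
    # smallest (x, y, original index) member
    order = np.lexsort((np.arange(n), xy[:, 1], xy[:, 0]))
    remap: dict[int, int] = {}
    for idx in order:
        remap.setdefault(labels[idx], len(remap))
    return np.array([remap[l] for l in labels], dtype=int)


def build_site_data(
    records: pd.DataFrame,
    site_labels: np.ndarray | None = None,
    covariate_table: pd.DataFrame | None = None,
) -> list[SiteData]:
    """Reduce assigned sighting records to per-site replicate count data.

    Survey raw values may be multiple-choice strings (encoded via
    :func:`encode_survey_response`) or already-numeric counts; report and
    expert raw values must be non-negative numbers.  Expert records within
    a site are summed into a single consensus count ``w`` (the expert
    protocol precludes double counting, so distinct records are distinct
    individuals); occupancy is "present" if the consensus is positive,
    "absent" if experts surveyed the site and found none, else "unknown".

    Sites with no citizen replicates are excluded with a warning: the
    model cannot attribute observation error there.

    ``covariate_table`` (optional) is indexed by site id or carries a
    ``site_id`` column; remaining columns become site covariates.
    """
    records = records.reset_index(drop=True)
    if site_labels is None:
        if "site_id" not in records.columns:
            raise ValueError("need site_labels or a site_id column")
        site_labels = records["site_id"].to_numpy()
    site_labels = np.asarray(site_labels)
    if len(site_labels) != len(records):
        raise ValueError("site_labels length mismatch")

    cov_lookup: Mapping[int, dict[str, float]] = {}
    if covariate_table is not None:
        tbl = covariate_table.set_index("site_id") if "site_id" in covariate_table.columns else covariate_table
        cov_lookup = {int(k): dict(v) for k, v in tbl.iterrows()}

    sites: list[SiteData] = []
    for sid in sorted(pd.unique(site_labels)):
        grp = records.loc[site_labels == sid]
        y, u = [], []
        w_total, expert_seen = 0, False
        study_area = ""
        for _, row in grp.iterrows():
            obs = row["observer_type"]
            if obs not in OBSERVER_TYPES:
                raise ValueError(f"unknown observer_type {obs!r}")
            raw = row["raw_value"]
            if obs == "survey":
                val = float(raw) if isinstance(raw, (int, float, np.number)) else encode_survey_response(raw)
                y.append(val)
            elif obs == "report":
                u.append(float(raw))
            else:
                w_total += int(raw)
                expert_seen = True
            if row.get("study_area", ""):
                study_area = str(row["study_area"])
        if not y and not u:
            logger.warning("site %s has no citizen replicates; excluded", sid)
            continue
        occ = ("present" if w_total > 0 else "absent") if expert_seen else "unknown"
        sites.append(
            SiteData(
                site_id=int(sid),
                y=np.array(y),
                u=np.array(u),
                w=w_total if expert_seen else None,
                expert_occupancy=occ,
                covariates=cov_lookup.get(int(sid), {}),
                study_area=study_area,
            )
        )
    names = {tuple(sorted(s.covariates)) for s in sites}
    if len(names) > 1:
        raise ValueError("inconsistent covariate names across sites")
    return sites


@dataclass(frozen=True)
class Standardizer:
    """Remembers the fitting data's mean/SD so new values standardize
    against the same frame (population-SD convention)."""

    mean: float
    sd: float

    def transform(self, values: Iterable[float]) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def inverse(self, standardized: Iterable[float]) -> np.ndarray:
        return np.asarray(standardized, dtype=float) * self.sd + self.mean


def standardize_covariate(values: Sequence[float]) -> tuple[np.ndarray, Standardizer]:
    """Center and scale to mean 0, SD 1 (population SD, ddof=0)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2 or np.unique(arr).size < 2:
        raise ValueError("need at least 2 distinct values to standardize")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=0))
    if sd == 0:
        raise ValueError("zero variance")
    scaler = Standardizer(mean, sd)
    return scaler.transform(arr), scaler


def expert_site_coverage(sites: Sequence[SiteData]) -> float:
    """Fraction of sites with an expert consensus count."""
    if not sites:
        raise ValueError("no sites")
    return sum(s.w is not None for s in sites) / len(sites)


def total_count_mass(sites: Sequence[SiteData]) -> float:
    """Sum of all encoded citizen and expert counts (conservation check)."""
    return float(
        sum(s.y.sum() + s.u.sum() + (s.w or 0) for s in sites)
    )
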