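"""Extent of occurrence (EOO), area of occupancy (AOO) and range-based screening.

EOO is the area of the minimum convex polygon around a species' localities;
AOO is 4 km² per occupied 2x2 km cell.  Both are measured on an azimuthal
equal-area projection centred (by default) on the species' point centroid, so
values are comparable across species.  The range-only IUCN Criterion B screen
maps these onto CR/EN/VU/LC, and species with EOO < 5000 km² are flagged as
endemic (the Criterion B cut-off for EN, and a natural break in the observed
EOO distribution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .geometry import laea_project

__all__ = [
    "Occurrence",
    "RangeSummary",
    "compute_eoo",
    "compute_aoo",
    "screen_criterion_b",
    "flag_endemic",
    "eoo_gap_profile",
    "summarize_ranges",
]

ENDEMIC_EOO_KM2 = 5000.0

# (eoo upper bound, aoo upper bound, category), most severe first
_CRITERION_B = [
    (100.0, 10.0, "CR"),
    (5000.0, 500.0, "EN"),
    (20000.0, 2000.0, "VU"),
]


@dataclass
class Occurrence:
    species_id: str
    lon: float
    lat: float
    date: str | None = None
    collector: str | None = None

    def __post_init__(self):
        if not (np.isfinite(self.lon) and np.isfinite(self.lat)):
            raise ValueError(f"{self.species_id}: non-finite coordinates")
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise ValueError(
                f"{self.species_id}: coordinates out of range ({self.lon}, {self.lat})"
            )


@dataclass
class RangeSummary:
    species_id: str
    eoo_km2: float
    aoo_km2: float
    n_points: int
    screened_status: str
    endemic: bool
    eoo_below_aoo: bool = False


def _as_lonlat(points) -> np.ndarray:
    if isinstance(points, np.ndarray):
        arr = np.asarray(points, dtype=float)
    elif len(points) and isinstance(points[0], Occurrence):
        arr = np.array([(p.lon, p.lat) for p in points], dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (n, 2) lon/lat")
    return arr


def compute_aoo(points, cell_km: float = 2.0, center: tuple | None = None) -> float:
    """AOO: cell_km² x 4/... i.e. cell_km**2 per distinct occupied cell, km².

    Cells live on an equal-area grid anchored at the projection origin (the
    origin sits at a cell centre, so a tight cluster of points around the
    species' centroid shares one cell).  The projection centre defaults to the
    point centroid; pass ``center`` to pin it (e.g. when comparing nested
    point sets).
    """
    pts = _as_lonlat(points)
    if len(pts) == 0:
        raise ValueError("AOO requires at least one occurrence")
    if center is None:
        center = tuple(pts.mean(axis=0))
    x, y = laea_project(pts[:, 0], pts[:, 1], center[0], center[1])
    ij = np.stack(
        [np.floor(x / cell_km + 0.5), np.floor(y / cell_km + 0.5)], axis=1
    )
    n_cells = len(np.unique(ij, axis=0))
    return float(n_cells * cell_km * cell_km)


def compute_eoo(points, center: tuple | None = None, cell_km: float = 2.0) -> float:
    """EOO: convex-hull area of the localities, km².

    Coincident or collinear point sets have a degenerate (zero-area) hull; the
    IUCN convention is that such ranges are measured by occupancy, so the AOO
    value is returned as a fallback.
    """
    pts = _as_lonlat(points)
    if len(pts) == 0:
        raise ValueError("EOO requires at least one occurrence")
    if center is None:
        center = tuple(pts.mean(axis=0))
    if len(pts) >= 3:
        x, y = laea_project(pts[:, 0], pts[:, 1], center[0], center[1])
        xy = np.stack([x, y], axis=1)
        try:
            hull = ConvexHull(xy)
        except Exception:  # all points collinear/coincident
            return compute_aoo(pts, cell_km=cell_km, center=center)
        if hull.volume > 0.0:  # in 2D, .volume is the area
            return float(hull.volume)
    return compute_aoo(pts, cell_km=cell_km, center=center)


def screen_criterion_b(eoo_km2: float, aoo_km2: float) -> str:
    """Range-threshold-only Criterion B screen (no subcriteria).

    CR if EOO < 100 or AOO < 10; EN if EOO < 5000 or AOO < 500;
    VU if EOO < 20000 or AOO < 2000; else LC.
    """
    if eoo_km2 < 0 or aoo_km2 < 0:
        raise ValueError("EOO and AOO must be non-negative")
    for eoo_max, aoo_max, category in _CRITERION_B:
        if eoo_km2 < eoo_max or aoo_km2 < aoo_max:
            return category
    return "LC"


def flag_endemic(eoo_km2: float) -> bool:
    """Endemism rule: EOO strictly below 5000 km²."""
    return eoo_km2 < ENDEMIC_EOO_KM2


def eoo_gap_profile(eoo_by_species: dict | pd.Series) -> pd.DataFrame:
    """Sorted EOO values with successive relative gaps, for natural-break inspection.

    For each consecutive pair in ascending EOO order the relative gap is
    (next - current) / current (0 where current is 0).  A pronounced maximum
    marks a natural break separating narrow-range from widespread species.
    """
    s = pd.Series(dict(eoo_by_species), dtype=float).sort_values()
    if len(s) < 2:
        raise ValueError("gap profile requires at least two species")
    vals = s.to_numpy()
    gaps = np.diff(vals)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(vals[:-1] > 0, gaps / vals[:-1], 0.0)
    return pd.DataFrame(
        {
            "species_id": s.index[:-1],
            "eoo_km2": vals[:-1],
            "next_eoo_km2": vals[1:],
            "gap_km2": gaps,
            "relative_gap": rel,
        }
    )


def hull_polygons(occurrences: pd.DataFrame):
    """Per-species convex hulls in lon/lat, for GeoJSON export.

    Species with fewer than 3 distinct localities yield their multipoint
    hull (a point or line).
    """
    from shapely.geometry import MultiPoint

    out = []
    for sp, grp in occurrences.groupby("species_id", sort=True):
        pts = MultiPoint(list(zip(grp["lon"], grp["lat"])))
        out.append((sp, pts.convex_hull))
    return out


def summarize_ranges(occurrences: pd.DataFrame) -> pd.DataFrame:
    """Per-species EOO, AOO, Criterion B screen and endemism flag.

    ``occurrences`` needs columns species_id, lon, lat.  The output flags
    species whose hull-based EOO fell below AOO (possible for thin hulls; the
    IUCN EOO>=AOO convention is reported, not enforced).
    """
    rows = []
    for sp, grp in occurrences.groupby("species_id", sort=True):
        pts = grp[["lon", "lat"]].to_numpy(float)
        center = tuple(pts.mean(axis=0))
        aoo = compute_aoo(pts, center=center)
        eoo = compute_eoo(pts, center=center)
        rows.append(
            RangeSummary(
                species_id=sp,
                eoo_km2=eoo,
                aoo_km2=aoo,
                n_points=len(pts),
                screened_status=screen_criterion_b(eoo, aoo),
                endemic=flag_endemic(eoo),
                eoo_below_aoo=eoo < aoo,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
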