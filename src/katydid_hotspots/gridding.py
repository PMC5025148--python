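"""Degree-grid (fishnet) construction and per-cell diversity metrics.

The study region is tessellated with cells of 1° longitude x 1° latitude
aligned to an integer graticule, clipped to the region ("coastline"), and each
occurrence record is assigned to exactly one cell by half-open membership.
Per occupied cell we count total, threatened (T >= 1, i.e. VU/EN/CR), endemic
(EOO < 5000 km²) and sensitive (LH = 3) species richness, and average the six
composite scores over the species present (species-level averaging: duplicate
records of a species in a cell do not weight the mean).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.validation import make_valid

from .geometry import polygon_area_km2
from .scoring import COMPOSITE_NAMES

__all__ = ["GridCell", "Fishnet", "build_fishnet", "assign_records", "cell_metrics"]


@dataclass
class GridCell:
    cell_id: str
    lon0: float
    lat0: float
    cell_deg: float
    clipped_polygon: object
    land_area_km2: float
    col: int  # longitude index on the graticule
    row: int  # latitude index on the graticule

    @property
    def bounds(self):
        return (self.lon0, self.lat0, self.lon0 + self.cell_deg, self.lat0 + self.cell_deg)

    @property
    def centroid_lonlat(self):
        c = self.clipped_polygon.centroid
        return (c.x, c.y)


@dataclass
class Fishnet:
    cells: list
    cell_deg: float
    origin: tuple
    index: dict = field(default_factory=dict)  # (col, row) -> GridCell

    def __post_init__(self):
        if not self.index:
            self.index = {(c.col, c.row): c for c in self.cells}

    def __len__(self):
        return len(self.cells)

    def cell_ids(self):
        return [c.cell_id for c in self.cells]


def _row_letter(i: int) -> str:
    """Spreadsheet-style letters A, B, ..., Z, AA, AB, ... (cosmetic labels)."""
    letters = string.ascii_uppercase
    out = ""
    i = int(i)
    while True:
        out = letters[i % 26] + out
        i = i // 26 - 1
        if i < 0:
            return out


def build_fishnet(region, cell_deg: float = 1.0, origin=(0.0, 0.0)) -> Fishnet:
    """All graticule-aligned cells intersecting ``region``, clipped to it.

    Cells with zero land intersection are excluded.  Labels are graticule
    style: a letter per latitude row (A = northernmost row present) and a
    number per longitude column (1 = westernmost).  Labels are cosmetic and
    never used in computation.
    """
    if region is None or region.is_empty:
        raise ValueError("region polygon is empty")
    region = make_valid(region)
    ox, oy = origin
    minx, miny, maxx, maxy = region.bounds
    i0 = int(np.floor((minx - ox) / cell_deg))
    i1 = int(np.ceil((maxx - ox) / cell_deg))
    j0 = int(np.floor((miny - oy) / cell_deg))
    j1 = int(np.ceil((maxy - oy) / cell_deg))
    raw = []
    for i in range(i0, i1):
        lon0 = ox + i * cell_deg
        for j in range(j0, j1):
            lat0 = oy + j * cell_deg
            cell = box(lon0, lat0, lon0 + cell_deg, lat0 + cell_deg)
            clipped = cell.intersection(region)
            if clipped.is_empty or clipped.area == 0.0:
                continue
            raw.append((i, j, lon0, lat0, clipped))
    if not raw:
        return Fishnet(cells=[], cell_deg=cell_deg, origin=(ox, oy))
    max_row = max(j for _, j, *_ in raw)
    min_col = min(i for i, *_ in raw)
    cells = []
    for i, j, lon0, lat0, clipped in raw:
        label = f"{_row_letter(max_row - j)}{i - min_col + 1}"
        cells.append(
            GridCell(
                cell_id=label,
                lon0=lon0,
                lat0=lat0,
                cell_deg=cell_deg,
                clipped_polygon=clipped,
                land_area_km2=polygon_area_km2(clipped),
                col=i,
                row=j,
            )
        )
    cells.sort(key=lambda c: (-c.row, c.col))
    return Fishnet(cells=cells, cell_deg=cell_deg, origin=(ox, oy))


def assign_records(records: pd.DataFrame, grid: Fishnet):
    """Map each record to its grid cell by half-open [lon0, lon0+d) x [lat0, lat0+d).

    A record exactly on an interior cell edge belongs to the cell on its
    east/north side.  Returns (assignments, unassigned): ``assignments`` is a
    copy of ``records`` with a ``cell_id`` column for records landing in a grid
    cell; ``unassigned`` holds the rest (reported, never silently dropped).
    """
    ox, oy = grid.origin
    d = grid.cell_deg
    cols = np.floor((records["lon"].to_numpy(float) - ox) / d).astype(int)
    rows = np.floor((records["lat"].to_numpy(float) - oy) / d).astype(int)
    cell_ids = [
        grid.index[(c, r)].cell_id if (c, r) in grid.index else None
        for c, r in zip(cols, rows)
    ]
    out = records.copy()
    out["cell_id"] = cell_ids
    assigned = out[out["cell_id"].notna()].copy()
    unassigned = out[out["cell_id"].isna()].drop(columns=["cell_id"])
    return assigned, unassigned


def species_sets(assigned: pd.DataFrame) -> dict:
    """Deduplicated species set per occupied cell."""
    return {
        cid: set(grp["species_id"]) for cid, grp in assigned.groupby("cell_id", sort=True)
    }


def cell_metrics(
    assigned: pd.DataFrame,
    scores: pd.DataFrame,
    ranges: pd.DataFrame,
    grid: Fishnet,
) -> pd.DataFrame:
    """Per-cell richness counts and mean composite scores.

    One row per grid cell.  Unoccupied cells carry NaN metrics ("no data",
    distinct from zero) and ``has_data = False``.  Every species present in a
    cell must have a score row; DD species must have been excluded upstream.
    """
    score_idx = scores.set_index("species_id")
    endemic_of = dict(zip(ranges["species_id"], ranges["endemic"].astype(bool)))
    sets = species_sets(assigned)
    n_rec = assigned.groupby("cell_id").size().to_dict()

    missing = set().union(*sets.values()) - set(score_idx.index) if sets else set()
    if missing:
        raise ValueError(f"species without scores present in cells: {sorted(missing)}")

    rows = []
    for cell in grid.cells:
        cid = cell.cell_id
        spp = sorted(sets.get(cid, ()))
        row = {
            "cell_id": cid,
            "land_area_km2": cell.land_area_km2,
            "centroid_lon": cell.centroid_lonlat[0],
            "centroid_lat": cell.centroid_lonlat[1],
            "n_records": int(n_rec.get(cid, 0)),
            "has_data": bool(spp),
        }
        if spp:
            sub = score_idx.loc[spp]
            row["richness_total"] = len(spp)
            row["richness_threatened"] = int((sub["T"] >= 1).sum())
            row["richness_endemic"] = int(sum(endemic_of.get(s, False) for s in spp))
            row["richness_sensitive"] = int((sub["LH"] == 3).sum())
            for name in COMPOSITE_NAMES:
                row[f"mean_{name}"] = float(sub[name].mean())
        else:
            for k in (
                "richness_total",
                "richness_threatened",
                "richness_endemic",
                "richness_sensitive",
                *[f"mean_{n}" for n in COMPOSITE_NAMES],
            ):
                row[k] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
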