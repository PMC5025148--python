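"""Spherical geometry helpers shared by the range, gridding and spatial modules.

All geographic coordinates are WGS84 decimal degrees (lon, lat); all areas are
km² and all distances km unless noted.  Areas are measured on the authalic
sphere through a Lambert azimuthal equal-area (LAEA) projection centred on the
feature being measured, so species ranges and grid cells are comparable across
latitudes without a fixed national CRS.
"""

from __future__ import annotations

import math

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import transform as shapely_transform

#: authalic Earth radius, km
EARTH_RADIUS_KM = 6371.0088


def laea_project(lon, lat, lon0: float, lat0: float):
    """Lambert azimuthal equal-area forward projection (sphere).

    Parameters are degrees; returns (x, y) in km.  Equal-area by construction,
    so planar areas of projected geometries are spherical areas.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lam, phi = np.radians(lon), np.radians(lat)
    lam0, phi0 = math.radians(lon0), math.radians(lat0)
    dlam = lam - lam0
    denom = 1.0 + math.sin(phi0) * np.sin(phi) + math.cos(phi0) * np.cos(phi) * np.cos(dlam)
    # antipode maps to infinity; clip to keep downstream hulls finite
    denom = np.maximum(denom, 1e-12)
    k = np.sqrt(2.0 / denom)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dlam)
    y = EARTH_RADIUS_KM * k * (
        math.cos(phi0) * np.sin(phi) - math.sin(phi0) * np.cos(phi) * np.cos(dlam)
    )
    return x, y


def project_geometry(geom, lon0: float, lat0: float):
    """Project a shapely lon/lat geometry to the LAEA plane centred at (lon0, lat0)."""
    return shapely_transform(lambda x, y, z=None: laea_project(x, y, lon0, lat0), geom)


def _densify_ring(coords, max_step_deg: float):
    """Insert vertices so no edge spans more than ``max_step_deg`` degrees.

    Long graticule-aligned edges must be densified before projection or the
    projected polygon cuts corners and under/over-states spherical area.
    """
    out = []
    coords = list(coords)
    for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
        seg = max(abs(x1 - x0), abs(y1 - y0))
        n = max(1, int(math.ceil(seg / max_step_deg)))
        for i in range(n):
            t = i / n
            out.append((x0 + t * (x1 - x0), y0 + t * (y1 - y0)))
    out.append(coords[-1])
    return out


def densify_polygon(poly: Polygon, max_step_deg: float = 0.05) -> Polygon:
    shell = _densify_ring(poly.exterior.coords, max_step_deg)
    holes = [_densify_ring(r.coords, max_step_deg) for r in poly.interiors]
    return Polygon(shell, holes)


def polygon_area_km2(geom, lon0: float | None = None, lat0: float | None = None) -> float:
    """Equal-area surface area of a lon/lat polygon (or multipolygon), km².

    The projection centre defaults to the geometry's own centroid, minimising
    distortion for the feature at hand.
    """
    if geom.is_empty:
        return 0.0
    if lon0 is None or lat0 is None:
        c = geom.centroid
        lon0, lat0 = c.x, c.y
    polys = getattr(geom, "geoms", [geom])
    total = 0.0
    for p in polys:
        if p.is_empty or p.area == 0.0:
            continue
        total += project_geometry(densify_polygon(p), lon0, lat0).area
    return total


def great_circle_km(lon1, lat1, lon2, lat2):
    """Great-circle distance, km (haversine); accepts arrays."""
    lon1, lat1 = np.radians(lon1), np.radians(lat1)
    lon2, lat2 = np.radians(lon2), np.radians(lat2)
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_great_circle_km(lons, lats) -> np.ndarray:
    """Symmetric matrix of great-circle distances between points, km."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return great_circle_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
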