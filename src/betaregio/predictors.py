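"""Derivation of environmental predictor layers and per-site extraction.

Nine predictors drive the dissimilarity model: mean annual sea-surface
temperature and its annual range, mean annual sea-surface salinity and its
range, bathymetry (positive depth, m), bathymetric slope (deg), aspect
decomposed into eastness/northness, and distance to shore (km).  Geographic
distances are great-circle (haversine) on a spherical Earth of radius
6371 km.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .containers import GridSpec, PredictorStack

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
#: length of one degree of a great circle on the spherical Earth, km
KM_PER_DEGREE = np.pi * EARTH_RADIUS_KM / 180.0

__all__ = [
    "monthly_to_climatology",
    "aspect_decompose",
    "terrain_slope",
    "terrain_aspect",
    "distance_to_shore",
    "geographic_distance",
    "extract_at_sites",
    "EARTH_RADIUS_KM",
    "KM_PER_DEGREE",
]


def monthly_to_climatology(monthly: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Annual mean and annual range (max - min) from a 12-month stack.

    ``monthly`` has shape (12, n_rows, n_cols); a cell missing in any month
    is missing in both outputs.
    """
    monthly = np.asarray(monthly, dtype=float)
    if monthly.ndim != 3 or monthly.shape[0] != 12:
        raise ValueError("monthly climatology requires exactly 12 co-registered layers")
    mean = monthly.mean(axis=0)  # NaN propagates
    rng = monthly.max(axis=0) - monthly.min(axis=0)
    return mean, rng


def aspect_decompose(aspect_deg) -> tuple[np.ndarray, np.ndarray]:
    """Split an aspect angle (degrees clockwise from north) into eastness and
    northness components: eastness = sin(aspect), northness = cos(aspect).

    Values outside [0, 360) are wrapped modulo 360 with a warning.
    """
    a = np.asarray(aspect_deg, dtype=float)
    with np.errstate(invalid="ignore"):
        out_of_range = (a < 0) | (a >= 360)
    if np.any(out_of_range & np.isfinite(a)):
        warnings.warn("aspect values outside [0, 360) wrapped modulo 360", stacklevel=2)
        a = np.mod(a, 360.0)
    rad = np.deg2rad(a)
    return np.sin(rad), np.cos(rad)


def _cell_size_m(grid: GridSpec) -> tuple[np.ndarray, float]:
    """Per-row east-west cell size and the north-south cell size, in meters."""
    lat = grid.lat_centers
    dx = grid.dlon * KM_PER_DEGREE * 1000.0 * np.cos(np.deg2rad(lat))
    dy = grid.dlat * KM_PER_DEGREE * 1000.0
    return dx, dy


def _depth_gradient(depth: np.ndarray, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """d(depth)/dx (east) and d(depth)/dy (north) in m/m, central differences."""
    depth = np.asarray(depth, dtype=float)
    dx_m, dy_m = _cell_size_m(grid)
    # axis 0 runs north -> south, so the northward derivative is the negated
    # row-wise gradient
    ddepth_drow, ddepth_dcol = np.gradient(depth)
    ddx = ddepth_dcol / dx_m[:, None]
    ddy = -ddepth_drow / dy_m
    return ddx, ddy


def terrain_slope(depth: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Bathymetric slope in degrees from central differences of depth.

    Cell size is converted to meters with a latitude-dependent degree
    length; single-row/column edges fall back to one-sided differences
    (``np.gradient`` behavior).
    """
    ddx, ddy = _depth_gradient(depth, grid)
    return np.degrees(np.arctan(np.hypot(ddx, ddy)))


def terrain_aspect(depth: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Azimuth of the steepest downslope direction of the seabed, degrees
    clockwise from north in [0, 360).

    Flat cells get aspect 0 by convention.
    """
    ddx, ddy = _depth_gradient(depth, grid)
    # seabed elevation is -depth; steepest descent of elevation points along
    # +grad(depth)
    az = np.degrees(np.arctan2(ddx, ddy))
    az = np.mod(az, 360.0)
    az[np.hypot(ddx, ddy) == 0] = 0.0
    return az


def _latlon_to_xyz(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lam, phi = np.deg2rad(lon), np.deg2rad(lat)
    return np.column_stack(
        (np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi))
    )


def distance_to_shore(sea_mask: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Great-circle distance (km) from each sea cell center to the nearest
    land cell center; NaN on land.
    """
    sea_mask = np.asarray(sea_mask, dtype=bool)
    if not (~sea_mask).any():
        raise ValueError("distance to shore undefined: mask contains no land cells")
    if not sea_mask.any():
        raise ValueError("mask contains no sea cells")
    lon, lat = grid.cell_coords()
    land_xyz = _latlon_to_xyz(lon[~sea_mask], lat[~sea_mask])
    sea_xyz = _latlon_to_xyz(lon[sea_mask], lat[sea_mask])
    chord, _ = cKDTree(land_xyz).query(sea_xyz)
    arc_km = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))
    out = np.full(sea_mask.shape, np.nan)
    out[sea_mask] = arc_km
    return out


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance between coordinate arrays, km (broadcasting)."""
    lon1, lat1 = np.deg2rad(lon1), np.deg2rad(lat1)
    lon2, lat2 = np.deg2rad(lon2), np.deg2rad(lat2)
    dphi = lat2 - lat1
    dlam = lon2 - lon1
    h = np.sin(dphi / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def geographic_distance(lon, lat) -> np.ndarray:
    """Symmetric matrix of pairwise great-circle distances (km) among sites."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude outside [-90, 90]")
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)


def extract_at_sites(stack: PredictorStack, sites: pd.DataFrame) -> pd.DataFrame:
    """Nearest-cell-center extraction of every layer at each site.

    ``sites`` needs columns site_id, lon, lat.  Sites falling on missing
    (land) cells are dropped with a logged count.
    """
    row, col = stack.grid.nearest_cell(sites["lon"].to_numpy(), sites["lat"].to_numpy())
    keep = stack.sea_mask[row, col]
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("extract_at_sites: dropped %d site(s) on missing cells", n_dropped)
    if not keep.any():
        raise ValueError("all sites fall on missing cells; empty site table")
    out = sites.loc[keep, ["site_id", "lon", "lat"]].reset_index(drop=True)
    for name, arr in stack.layers.items():
        out[name] = arr[row[keep], col[keep]]
    return out
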