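"""Nonmetric multidimensional scaling and gradient mapping.

NMDS embeds a dissimilarity matrix in few dimensions so that embedded
distances preserve the rank order of the input dissimilarities; misfit is
Kruskal's stress-1,

    stress = sqrt( sum (dhat_ij - delta_ij)^2 / sum delta_ij^2 )

where delta are configuration distances and dhat the isotonic (monotone)
regression of delta on the input dissimilarities.  The optimizer is SMACOF
with an isotonic-regression disparity step; the best of ``n_starts``
random initializations is returned and every per-start stress trace is
kept (traces are non-increasing by construction: an iteration that would
increase stress terminates its start).

Positions are turned into colors with a fixed two-axis rule so that nearby
points in ordination space — compositionally similar assemblages — map to
similar colors, and a spatial gradient-magnitude ("slope of beta
diversity") raster marks sharp compositional transitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.linalg import orthogonal_procrustes
from sklearn.isotonic import IsotonicRegression

from .containers import GridSpec
from .predictors import KM_PER_DEGREE

__all__ = [
    "Ordination",
    "nmds",
    "procrustes_align",
    "coords_to_colors",
    "turnover_slope_map",
    "place_by_nearest",
]


@dataclass
class Ordination:
    coords: np.ndarray                  # (n, n_dim)
    stress: float                       # Kruskal stress-1 of the best start
    n_starts: int
    best_start: int                     # index of the winning start
    seed: int | None
    stress_traces: list[np.ndarray] = field(repr=False, default_factory=list)


def _stress1(dhat: np.ndarray, delta: np.ndarray) -> float:
    denom = float(np.sum(delta**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dhat - delta) ** 2) / denom))


def _isotonic_disparities(d: np.ndarray, delta: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Monotone regression of configuration distances on dissimilarities.

    ``order`` sorts pairs by (dissimilarity, configuration distance): ties
    in the input dissimilarity are resolved by the secondary ordering on
    delta, then pooled-adjacent-violators runs on the sorted sequence.
    """
    iso = IsotonicRegression(increasing=True)
    dhat = np.empty_like(delta)
    fitted = iso.fit_transform(np.arange(order.size), delta[order])
    dhat[order] = fitted
    return dhat


def classical_scaling(d: np.ndarray, n_dim: int = 2) -> np.ndarray:
    """Classical (metric) multidimensional scaling: eigendecomposition of
    the double-centered squared-dissimilarity matrix.  Used as the
    deterministic first start of NMDS (the standard warm start)."""
    n = d.shape[0]
    j = np.eye(n) - 1.0 / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:n_dim]
    return v[:, idx] * np.sqrt(np.maximum(w[idx], 0.0))


def _smacof_start(d: np.ndarray, n: int, n_dim: int, max_iter: int, tol: float,
                  rng: np.random.Generator,
                  init: np.ndarray | None = None
                  ) -> tuple[np.ndarray, float, np.ndarray]:
    X = rng.uniform(-1.0, 1.0, size=(n, n_dim)) if init is None else init.copy()
    delta = pdist(X)
    trace = []
    stress_prev = np.inf
    X_best, delta_best = X, delta
    for _ in range(max_iter):
        order = np.lexsort((delta, d))
        dhat = _isotonic_disparities(d, delta, order)
        # stress-1 uses the raw isotonic fit; the Guttman update below uses
        # disparities rescaled to the configuration's scale (avoids shrinkage)
        stress = _stress1(dhat, delta)
        ss = float(np.sum(dhat**2))
        if ss > 0:
            dhat = dhat * np.sqrt(np.sum(delta**2) / ss)
        if not stress < stress_prev - tol:
            if stress < stress_prev:
                trace.append(stress)
                X_best, stress_prev = X, stress
            break
        trace.append(stress)
        X_best, delta_best, stress_prev = X, delta, stress
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(delta > 0, dhat / delta, 0.0)
        B = -squareform(ratio)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n
        delta = pdist(X)
    return X_best, stress_prev, np.asarray(trace)


def nmds(d: np.ndarray, n_dim: int = 2, n_starts: int = 100, max_iter: int = 300,
         tol: float = 1e-7, seed: int | None = None,
         classical_start: bool = True) -> Ordination:
    """Best-of-``n_starts`` nonmetric MDS of a symmetric dissimilarity
    matrix; random start ``s`` uses ``seed + s``.

    With ``classical_start`` (default) the first start is initialized from
    the classical-scaling configuration instead of at random — the
    standard warm start, which anchors the nonmetric solution to the
    metric geometry when several configurations have similar stress."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if n < n_dim + 1:
        raise ValueError("need at least n_dim + 1 items")
    dc = squareform(d, checks=False)
    if np.ptp(dc) == 0:
        warnings.warn("all dissimilarities equal; NMDS configuration is degenerate",
                      stacklevel=2)
    base = 0 if seed is None else int(seed)
    best = None
    traces = []
    warm = classical_scaling(d, n_dim) if classical_start else None
    for s in range(n_starts):
        rng = np.random.default_rng(base + s)
        init = warm if (s == 0 and warm is not None) else None
        X, stress, trace = _smacof_start(dc, n, n_dim, max_iter, tol, rng,
                                         init=init)
        traces.append(trace)
        if best is None or stress < best[1]:
            best = (X, stress, s)
    X, stress, s = best
    return Ordination(coords=X - X.mean(axis=0), stress=stress, n_starts=n_starts,
                      best_start=s, seed=seed, stress_traces=traces)


def procrustes_align(reference: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, float]:
    """Align ``other`` onto ``reference`` by translation, rotation/reflection
    and uniform scale; returns (aligned coordinates, residual sum of squares).
    """
    a = np.asarray(reference, dtype=float)
    b = np.asarray(other, dtype=float)
    if a.shape != b.shape:
        raise ValueError("configurations must have the same shape")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - mu_a, b - mu_b
    R, _ = orthogonal_procrustes(b0, a0)
    rotated = b0 @ R
    denom = float(np.sum(rotated * rotated))
    scale = float(np.sum(rotated * a0)) / denom if denom > 0 else 1.0
    aligned = scale * rotated + mu_a
    residual = float(np.sum((aligned - a) ** 2))
    return aligned, residual


def coords_to_colors(coords: np.ndarray) -> np.ndarray:
    """Deterministic 2-axis-to-RGB rule: min-max scale each axis to [0, 1]
    (a degenerate zero-range axis becomes the constant 0.5), then
    color = (axis1, axis2, 1 - (axis1 + axis2)/2), clamped to [0, 1]."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords_to_colors expects n x 2 coordinates")
    scaled = np.empty_like(coords)
    for k in range(2):
        lo, hi = np.nanmin(coords[:, k]), np.nanmax(coords[:, k])
        if hi > lo:
            scaled[:, k] = (coords[:, k] - lo) / (hi - lo)
        else:
            scaled[:, k] = 0.5
    blue = 1.0 - (scaled[:, 0] + scaled[:, 1]) / 2.0
    return np.clip(np.column_stack([scaled[:, 0], scaled[:, 1], blue]), 0.0, 1.0)


def turnover_slope_map(coord_layers: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Spatial gradient magnitude of the ordination axes, per grid cell.

    ``coord_layers`` has shape (n_axes, n_rows, n_cols); the result is
    sqrt(sum over axes of (d axis/dx)^2 + (d axis/dy)^2) with distances in
    km (latitude-dependent east-west cell size).  High values mark sharp
    compositional transitions; cells without valid neighbors stay missing.
    """
    coord_layers = np.asarray(coord_layers, dtype=float)
    if coord_layers.ndim != 3:
        raise ValueError("coord_layers must be (n_axes, n_rows, n_cols)")
    lat = grid.lat_centers
    dx_km = grid.dlon * KM_PER_DEGREE * np.cos(np.deg2rad(lat))  # per row
    dy_km = grid.dlat * KM_PER_DEGREE
    total = np.zeros(coord_layers.shape[1:])
    for layer in coord_layers:
        grow, gcol = np.gradient(layer)
        gx = gcol / dx_km[:, None]
        gy = -grow / dy_km
        total += gx**2 + gy**2
    return np.sqrt(total)


def place_by_nearest(coords_sub: np.ndarray, features_sub: np.ndarray,
                     features_rest: np.ndarray) -> np.ndarray:
    """Place held-out items at the coordinates of their nearest neighbor in
    (standardized) feature space — the large-grid NMDS strategy."""
    from scipy.spatial import cKDTree

    mu = features_sub.mean(axis=0)
    sd = features_sub.std(axis=0)
    sd[sd == 0] = 1.0
    tree = cKDTree((features_sub - mu) / sd)
    _, idx = tree.query((features_rest - mu) / sd)
    return coords_sub[idx]
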