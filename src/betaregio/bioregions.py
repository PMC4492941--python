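"""Fuzzy bioregion delineation on ordination coordinates.

Fuzzy C-means (FCM) assigns each item a graded membership u_ik in [0, 1]
to each of k regions (rows sum to 1), minimizing

    J = sum_i sum_k u_ik^m ||x_i - c_k||^2

with fuzziness m (default 2, within the commonly recommended 1.5-3 range)
by alternating the standard membership and centroid updates.  Clustering
runs on NMDS coordinates so region centroids live in ordination space and
can be colored by the same rule as the cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .ordination import coords_to_colors

logger = logging.getLogger(__name__)

__all__ = [
    "FuzzyPartition",
    "fuzzy_cmeans",
    "hard_assignment",
    "region_colors",
    "radial_profile",
]


@dataclass
class FuzzyPartition:
    memberships: np.ndarray            # (n, k), rows sum to 1
    centroids: np.ndarray              # (k, n_dim) in ordination space
    m: float
    objective: float                   # final J
    n_iter: int
    objective_trace: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def _memberships(x: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    d2 = cdist(x, centroids, "sqeuclidean")
    zero = d2 <= 1e-300
    u = np.zeros_like(d2)
    any_zero = zero.any(axis=1)
    if any_zero.any():
        # limit rule: a point on a centroid belongs to it entirely
        rows = np.nonzero(any_zero)[0]
        u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    rest = ~any_zero
    if rest.any():
        p = 1.0 / (m - 1.0)
        inv = d2[rest] ** -p
        u[rest] = inv / inv.sum(axis=1, keepdims=True)
    return u


def _objective(x, centroids, u, m) -> float:
    d2 = cdist(x, centroids, "sqeuclidean")
    return float(np.sum((u**m) * d2))


def fuzzy_cmeans(x: np.ndarray, k: int = 3, m: float = 2.0, tol: float = 1e-9,
                 max_iter: int = 300, n_init: int = 20,
                 seed: int | None = None) -> FuzzyPartition:
    """Best-of-``n_init`` fuzzy C-means; restart r uses ``seed + r``.

    Initial centroids are k distinct data points drawn per restart; the
    objective J is non-increasing across iterations within a restart
    (asserted) and the restart with lowest final J wins.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("coordinates must be 2-D (n_items, n_dim)")
    n = x.shape[0]
    if n <= k:
        raise ValueError("need more items than clusters")
    if m <= 1:
        raise ValueError("fuzziness m must exceed 1")
    base = 0 if seed is None else int(seed)
    best: FuzzyPartition | None = None
    for r in range(n_init):
        rng = np.random.default_rng(base + r)
        centroids = x[rng.choice(n, size=k, replace=False)]
        trace = []
        j_prev = np.inf
        u = _memberships(x, centroids, m)
        for it in range(max_iter):
            um = u**m
            centroids = (um.T @ x) / um.sum(axis=0)[:, None]
            u = _memberships(x, centroids, m)
            j = _objective(x, centroids, u, m)
            assert j <= j_prev + 1e-9 * (1 + abs(j)), "FCM objective increased"
            trace.append(j)
            if j_prev - j < tol * (1.0 + abs(j)):
                break
            j_prev = j
        part = FuzzyPartition(
            memberships=u, centroids=centroids, m=m, objective=trace[-1],
            n_iter=len(trace), objective_trace=np.asarray(trace),
        )
        if best is None or part.objective < best.objective:
            best = part
    return best


def hard_assignment(part: FuzzyPartition) -> np.ndarray:
    """Crisp region labels (0-based) by maximum membership; ties go to the
    lowest region index and are logged."""
    u = part.memberships
    labels = u.argmax(axis=1)
    is_max = u == u.max(axis=1, keepdims=True)
    ties = is_max.sum(axis=1) > 1
    if ties.any():
        logger.info("hard_assignment: %d tie(s) broken toward the lowest region index",
                    int(ties.sum()))
    return labels


def region_colors(part: FuzzyPartition) -> np.ndarray:
    """One RGB triple per region: the cell color rule applied to the region
    centroids in ordination space."""
    return coords_to_colors(part.centroids)


def radial_profile(part: FuzzyPartition, env: pd.DataFrame) -> pd.DataFrame:
    """Membership-weighted environmental profile of each region.

    For region k and variable v the scaled profile is
    sum_i u_ik z_iv / sum_i u_ik with z the min-max scaled variable (so all
    variables share one radial axis); the membership-weighted raw means are
    reported alongside.  Rows of ``env`` must align with partition items.
    """
    if len(env) != part.memberships.shape[0]:
        raise ValueError("environmental table rows must align with partition items")
    u = part.memberships
    totals = u.sum(axis=0)
    vals = env.to_numpy(dtype=float)
    lo, hi = np.nanmin(vals, axis=0), np.nanmax(vals, axis=0)
    rng = np.where(hi > lo, hi - lo, 1.0)
    z = np.where(hi > lo, (vals - lo) / rng, 0.5)
    rows = []
    for k in range(part.k):
        if totals[k] <= 0:
            warnings.warn(f"region {k} has zero total membership; profile missing",
                          stacklevel=2)
            continue
        w = u[:, k] / totals[k]
        for v, name in enumerate(env.columns):
            rows.append({
                "region": k,
                "variable": name,
                "scaled_profile": float(w @ z[:, v]),
                "weighted_mean": float(w @ vals[:, v]),
                "total_membership": float(totals[k]),
            })
    return pd.DataFrame(rows)
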