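"""Turnover component of the Jaccard dissimilarity (beta_jtu).

For a pair of assemblages with A shared species, B unique to the first and
C unique to the second,

    beta_jtu = 2 * min(B, C) / (A + 2 * min(B, C))

Turnover isolates species replacement: a nested pair (min(B, C) = 0) has
zero turnover regardless of the richness difference, and joint absences
never contribute.  The nestedness component and the total Jaccard
dissimilarity are deliberately not part of the public surface.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
from scipy.spatial.distance import squareform

from .containers import OccurrenceMatrix

__all__ = ["PairCounts", "pair_counts", "jaccard_turnover", "turnover_matrix", "condensed"]


class PairCounts(NamedTuple):
    """Shared/unique species counts for one pair of assemblages."""

    A: int  # shared
    B: int  # unique to first
    C: int  # unique to second


def _as_binary(v) -> np.ndarray:
    v = np.asarray(v)
    if not np.isin(v, (0, 1)).all():
        raise ValueError("assemblage vectors must be strictly 0/1")
    return v.astype(bool)


def pair_counts(x, y) -> PairCounts:
    """Exact A/B/C set counts for two equal-length 0/1 vectors."""
    x, y = _as_binary(x), _as_binary(y)
    if x.shape != y.shape:
        raise ValueError("assemblage vectors must have equal length")
    return PairCounts(
        A=int((x & y).sum()),
        B=int((x & ~y).sum()),
        C=int((~x & y).sum()),
    )


def jaccard_turnover(c: PairCounts) -> float:
    """beta_jtu for one pair; the degenerate 0/0 case (at least one empty
    assemblage and no replacement) is defined as 0."""
    if min(c.A, c.B, c.C) < 0:
        raise ValueError("counts must be non-negative")
    m = min(c.B, c.C)
    denom = c.A + 2 * m
    if denom == 0:
        warnings.warn("beta_jtu 0/0 case (empty assemblage): defined as 0", stacklevel=2)
        return 0.0
    return 2.0 * m / denom


def turnover_matrix(occ: OccurrenceMatrix | np.ndarray) -> np.ndarray:
    """All pairwise beta_jtu among sites (vectorized).

    Returns a symmetric matrix with zero diagonal.  Sites with empty
    assemblages are flagged with a warning; their pairs take the 0/0
    convention value of 0.
    """
    x = occ.values if isinstance(occ, OccurrenceMatrix) else np.asarray(occ)
    if not np.isin(x, (0, 1)).all():
        raise ValueError("occurrence matrix must be strictly 0/1")
    x = x.astype(np.int64)
    n = x.shape[0]
    if n < 2:
        raise ValueError("turnover matrix requires at least 2 sites")
    richness = x.sum(axis=1)
    empty = np.nonzero(richness == 0)[0]
    if empty.size:
        warnings.warn(
            f"{empty.size} empty assemblage(s) at site index(es) {empty.tolist()}; "
            "their turnover values use the 0/0 := 0 convention",
            stacklevel=2,
        )
    a = x @ x.T
    b = richness[:, None] - a
    c = richness[None, :] - a
    m = np.minimum(b, c)
    denom = a + 2 * m
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, 2.0 * m / np.where(denom > 0, denom, 1), 0.0)
    np.fill_diagonal(beta, 0.0)
    return beta


def condensed(matrix: np.ndarray) -> np.ndarray:
    """Upper-triangle (condensed) storage of a symmetric dissimilarity
    matrix, length n(n-1)/2, pair order matching ``scipy`` conventions."""
    return squareform(matrix, checks=False)
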