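"""Indicator species analysis with the group-equalized indicator value.

For presence/absence data and site groups k with per-group occurrence
frequencies f_k = (occupied sites in group k) / (sites in group k):

    specificity  A_k = f_k / sum_j f_j        (group-equalized)
    fidelity     B_k = f_k
    IndVal^g_k   = sqrt(A_k * B_k)            (default convention)

A species' indicator region is the group maximizing the statistic.
Because A and B depend on within-group frequencies only, the statistic is
invariant to unequal group sizes (duplicating every site of one group
changes nothing).  Significance comes from permuting site-group labels;
the reported p uses the add-one estimator p = (1 + #{perm >= obs}) /
(1 + n_perm), so it is never exactly zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import OccurrenceMatrix

__all__ = ["indval_g", "permutation_test", "select_indicators", "indicator_analysis"]


def _freq_by_group(values: np.ndarray, labels: np.ndarray,
                   groups: np.ndarray) -> np.ndarray:
    """(k, n_species) within-group occurrence frequencies."""
    onehot = (labels[:, None] == groups[None, :]).astype(float)  # (n, k)
    sizes = onehot.sum(axis=0)
    return (onehot.T @ values) / sizes[:, None]


def _stats_from_freq(freq: np.ndarray, stat_form: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A, B and the indicator statistic per group x species."""
    total = freq.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(total > 0, freq / np.where(total > 0, total, 1.0), 0.0)
    b = freq
    if stat_form == "sqrt":
        stat = np.sqrt(a * b)
    elif stat_form == "product":
        stat = a * b
    else:
        raise ValueError("stat_form must be 'sqrt' or 'product'")
    return a, b, stat


def indval_g(occ: OccurrenceMatrix | np.ndarray, labels: np.ndarray,
             stat_form: str = "sqrt") -> pd.DataFrame:
    """IndVal^g per species x region.

    Returns one row per species and region with columns species, region,
    A (specificity), B (fidelity), stat, and best (True for the species'
    indicator region).  Species absent everywhere get stat 0 and are
    flagged with absent_everywhere=True.
    """
    values = occ.values if isinstance(occ, OccurrenceMatrix) else np.asarray(occ)
    species = occ.species if isinstance(occ, OccurrenceMatrix) else \
        [f"sp{i}" for i in range(values.shape[1])]
    labels = np.asarray(labels)
    if labels.shape[0] != values.shape[0]:
        raise ValueError("labels must align with occurrence rows")
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("indicator analysis needs at least 2 non-empty groups")
    freq = _freq_by_group(values.astype(float), labels, groups)
    a, b, stat = _stats_from_freq(freq, stat_form)
    absent = values.sum(axis=0) == 0
    best_region = stat.argmax(axis=0)
    rows = []
    for s, name in enumerate(species):
        for g, region in enumerate(groups):
            rows.append({
                "species": name,
                "region": region,
                "A": float(a[g, s]),
                "B": float(b[g, s]),
                "stat": float(stat[g, s]),
                "best": bool(g == best_region[s] and not absent[s]),
                "absent_everywhere": bool(absent[s]),
            })
    return pd.DataFrame(rows)


def permutation_test(occ: OccurrenceMatrix | np.ndarray, labels: np.ndarray,
                     n_perm: int = 9999, seed: int | None = None,
                     stat_form: str = "sqrt") -> pd.DataFrame:
    """Permutation p-value per species for its max-over-regions IndVal^g.

    Site labels are permuted ``n_perm`` times;
    p = (1 + #{permuted stat >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = (occ.values if isinstance(occ, OccurrenceMatrix) else np.asarray(occ)).astype(float)
    species = occ.species if isinstance(occ, OccurrenceMatrix) else \
        [f"sp{i}" for i in range(values.shape[1])]
    labels = np.asarray(labels)
    groups = np.unique(labels)
    _, _, stat = _stats_from_freq(_freq_by_group(values, labels, groups), stat_form)
    observed = stat.max(axis=0)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(values.shape[1], dtype=np.int64)
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        _, _, pstat = _stats_from_freq(_freq_by_group(values, perm, groups), stat_form)
        exceed += pstat.max(axis=0) >= observed - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame({"species": species, "stat": observed, "p": p})


def select_indicators(results: pd.DataFrame, stat_threshold: float = 0.6,
                      p_threshold: float = 0.001,
                      p_inclusive: bool = False) -> pd.DataFrame:
    """Indicator species table: stat strictly above ``stat_threshold`` and
    p strictly below ``p_threshold`` (``p_inclusive=True`` switches the p
    rule to <=), sorted by region then descending stat."""
    if results.empty:
        return results.copy()
    keep = results["stat"] > stat_threshold
    keep &= (results["p"] <= p_threshold) if p_inclusive else (results["p"] < p_threshold)
    return (
        results.loc[keep]
        .sort_values(["region", "stat"], ascending=[True, False])
        .reset_index(drop=True)
    )


def indicator_analysis(occ: OccurrenceMatrix, labels: np.ndarray,
                       n_perm: int = 9999, seed: int | None = None,
                       stat_form: str = "sqrt", stat_threshold: float = 0.6,
                       p_threshold: float = 0.001,
                       p_inclusive: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-species analysis: (all results, selected indicators).

    The results table has one row per species with its indicator region,
    statistic and permutation p-value.
    """
    per_region = indval_g(occ, labels, stat_form=stat_form)
    best = per_region[per_region["best"]][["species", "region", "A", "B", "stat"]]
    pvals = permutation_test(occ, labels, n_perm=n_perm, seed=seed, stat_form=stat_form)
    results = best.merge(pvals[["species", "p"]], on="species", how="left")
    selected = select_indicators(results, stat_threshold=stat_threshold,
                                 p_threshold=p_threshold, p_inclusive=p_inclusive)
    return results.reset_index(drop=True), selected
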