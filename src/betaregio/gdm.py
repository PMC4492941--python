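"""Generalized dissimilarity modeling (GDM).

A GDM is a nonlinear matrix regression predicting pairwise compositional
dissimilarity d_ij in [0, 1] from site-pair differences of monotonically
transformed predictors:

    eta_ij = a0 + sum_p sum_k a_pk * |I_pk(x_ip) - I_pk(x_jp)|
    mu_ij  = 1 - exp(-eta_ij)

with geographic distance entering as a predictor in its own right,
splined on the pair distance g_ij directly.  Each predictor is transformed
by three monotone I-spline basis functions with knots at the 0th, 50th and
100th percentiles of its observed values; coefficients (and the intercept)
are constrained non-negative, which makes predicted dissimilarity monotone
in every predictor difference.  Fitting minimizes the binomial-type
deviance

    D = 2 * sum_ij w_ij [ d ln(d/mu) + (1-d) ln((1-d)/(1-mu)) ]

with the 0*ln(0) := 0 convention and mu clamped away from {0, 1}.
Variable importance is the deviance increase when one predictor is
refitted out of the model (geographic distance is retained in every
partial model).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize, nnls

from .containers import OccurrenceMatrix, PredictorStack
from .predictors import haversine_km

__all__ = [
    "ISplineBasis",
    "SitePairTable",
    "GDMModel",
    "build_site_pairs",
    "fit",
    "deviance",
    "deviance_explained",
    "variable_importance",
    "transform_grid",
]

N_BASIS = 3  # three I-spline basis functions per predictor
_MU_EPS = 1e-6


class DegenerateBasisError(ValueError):
    """Raised when a predictor is constant and no monotone basis exists."""


# ---------------------------------------------------------------------------
# I-spline basis


class ISplineBasis:
    """Order-2 (quadratic) I-spline basis, 3 functions per predictor.

    Knots sit at the minimum, median and maximum of the observed values.
    Each basis function is monotone non-decreasing with I(min) = 0 and
    I(max) = 1; evaluation outside [min, max] clamps to the endpoint
    values.  Built as partial sums of degree-2 B-splines, the standard
    construction of integrated splines.
    """

    def __init__(self, knots: dict[str, np.ndarray]):
        self.knots = {k: np.asarray(v, dtype=float) for k, v in knots.items()}
        for name, q in self.knots.items():
            if len(q) != 3 or not (q[0] < q[2]):
                raise DegenerateBasisError(f"invalid knots for predictor {name!r}: {q}")

    @property
    def names(self) -> list[str]:
        return list(self.knots)

    @classmethod
    def from_values(cls, values: pd.DataFrame | dict) -> "ISplineBasis":
        """Knots from per-predictor observed values; constant predictors are
        dropped with a warning (no monotone basis exists for them)."""
        if isinstance(values, pd.DataFrame):
            values = {c: values[c].to_numpy(dtype=float) for c in values.columns}
        knots = {}
        for name, x in values.items():
            x = np.asarray(x, dtype=float)
            x = x[np.isfinite(x)]
            if x.size < 3:
                raise DegenerateBasisError(f"predictor {name!r} needs >= 3 values")
            q = np.percentile(x, [0, 50, 100])
            if q[0] == q[2]:
                warnings.warn(
                    f"predictor {name!r} is constant; dropped from basis", stacklevel=2
                )
                continue
            knots[name] = cls._regularize(q)
        if not knots:
            raise DegenerateBasisError("no predictor survived basis construction")
        return cls(knots)

    @staticmethod
    def _regularize(q: np.ndarray) -> np.ndarray:
        # interior knot must be strictly inside for a valid quadratic basis
        q = q.astype(float).copy()
        if not (q[0] < q[1] < q[2]):
            q[1] = 0.5 * (q[0] + q[2])
        return q

    @staticmethod
    def evaluate_knots(q: np.ndarray, x) -> np.ndarray:
        """(n, 3) I-spline values at ``x`` for one knot triple."""
        q0, q1, q2 = q
        x = np.clip(np.asarray(x, dtype=float), q0, q2)
        t = np.array([q0, q0, q0, q1, q2, q2, q2])
        dm = BSpline.design_matrix(x.ravel(), t, 2).toarray()  # (n, 4)
        # I_i = sum of B-splines j >= i; reversed cumulative sum, drop the
        # all-ones first column
        rev = np.cumsum(dm[:, ::-1], axis=1)[:, ::-1]
        return rev[:, 1:].reshape(x.shape + (N_BASIS,))

    def evaluate(self, name: str, x) -> np.ndarray:
        if name not in self.knots:
            raise KeyError(f"predictor {name!r} not in basis")
        return self.evaluate_knots(self.knots[name], x)

    def transform_table(self, values: pd.DataFrame) -> np.ndarray:
        """Stacked (n, 3 * n_predictors) I-spline transform of a site table."""
        cols = [self.evaluate(n, values[n].to_numpy(dtype=float)) for n in self.names]
        return np.concatenate(cols, axis=-1)


# ---------------------------------------------------------------------------
# Site-pair table

GEO = "geo"


@dataclass
class SitePairTable:
    """Design matrix over site pairs i<j for GDM fitting.

    ``X`` holds, per predictor, |I(x_i) - I(x_j)| for the three basis
    functions (for geographic distance: I(g_ij) directly); ``blocks`` maps
    predictor name to its column slice.
    """

    d: np.ndarray                      # (m,) observed dissimilarities
    X: np.ndarray = field(repr=False)  # (m, 3 * n_predictors)
    blocks: dict[str, slice]
    basis: ISplineBasis
    geo_knots: np.ndarray | None
    pair_idx: np.ndarray               # (m, 2) site positions, i < j
    weights: np.ndarray                # (m,)

    @property
    def predictor_names(self) -> list[str]:
        return list(self.blocks)

    @property
    def n_pairs(self) -> int:
        return self.d.shape[0]

    @classmethod
    def build(
        cls,
        d_matrix: np.ndarray,
        site_values: pd.DataFrame,
        geo: np.ndarray | None = None,
        weights: np.ndarray | None = None,
        basis: ISplineBasis | None = None,
    ) -> "SitePairTable":
        d_matrix = np.asarray(d_matrix, dtype=float)
        n = d_matrix.shape[0]
        if d_matrix.shape != (n, n) or len(site_values) != n:
            raise ValueError("dissimilarity matrix and site table orderings mismatch")
        if geo is not None and np.asarray(geo).shape != (n, n):
            raise ValueError("geographic distance matrix ordering mismatch")
        if basis is None:
            basis = ISplineBasis.from_values(
                site_values[[c for c in site_values.columns if c not in ("site_id", "lon", "lat")]]
            )
        ii, jj = np.triu_indices(n, k=1)
        d = d_matrix[ii, jj]
        if np.any((d < 0) | (d > 1)):
            raise ValueError("dissimilarities must lie in [0, 1]")
        T = basis.transform_table(site_values)          # (n, 3p)
        X_env = np.abs(T[ii] - T[jj])
        blocks = {
            name: slice(3 * k, 3 * k + 3) for k, name in enumerate(basis.names)
        }
        geo_knots = None
        if geo is not None:
            g = np.asarray(geo, dtype=float)[ii, jj]
            geo_knots = ISplineBasis._regularize(np.percentile(g, [0, 50, 100]))
            X_geo = ISplineBasis.evaluate_knots(geo_knots, g)
            X = np.concatenate([X_env, X_geo], axis=1)
            blocks[GEO] = slice(X_env.shape[1], X_env.shape[1] + N_BASIS)
        else:
            X = X_env
        w = np.ones(len(d)) if weights is None else np.asarray(weights, dtype=float)
        return cls(
            d=d, X=X, blocks=blocks, basis=basis, geo_knots=geo_knots,
            pair_idx=np.column_stack((ii, jj)), weights=w,
        )

    def drop_predictor(self, name: str) -> "SitePairTable":
        """Copy of the table without one predictor's columns (for the
        leave-one-out importance refits)."""
        if name not in self.blocks:
            raise KeyError(name)
        keep = [n for n in self.blocks if n != name]
        cols = np.concatenate([np.arange(self.X.shape[1])[self.blocks[n]] for n in keep])
        new_blocks = {n: slice(3 * k, 3 * k + 3) for k, n in enumerate(keep)}
        basis = ISplineBasis({n: self.basis.knots[n] for n in keep if n != GEO}) \
            if any(n != GEO for n in keep) else self.basis
        return SitePairTable(
            d=self.d, X=self.X[:, cols], blocks=new_blocks, basis=basis,
            geo_knots=self.geo_knots if GEO in keep else None,
            pair_idx=self.pair_idx, weights=self.weights,
        )


def build_site_pairs(
    occ: OccurrenceMatrix,
    sites: pd.DataFrame,
    turn: np.ndarray,
    geo: np.ndarray | None = None,
) -> SitePairTable:
    """Assemble the GDM site-pair table from occurrences, per-site predictor
    values, the observed turnover matrix and pairwise geographic distances.

    Sites with empty assemblages are excluded (their turnover is defined by
    convention only, not informative for fitting).
    """
    n = occ.n_sites
    if len(sites) != n or np.asarray(turn).shape != (n, n):
        raise ValueError("occurrence, site table and turnover matrix orderings mismatch")
    keep = occ.values.sum(axis=1) > 0
    idx = np.nonzero(keep)[0]
    pred_cols = [c for c in sites.columns if c not in ("site_id", "lon", "lat")]
    sub_sites = sites.iloc[idx].reset_index(drop=True)[pred_cols]
    sub_turn = np.asarray(turn, dtype=float)[np.ix_(idx, idx)]
    sub_geo = None if geo is None else np.asarray(geo, dtype=float)[np.ix_(idx, idx)]
    return SitePairTable.build(sub_turn, sub_sites, geo=sub_geo)


# ---------------------------------------------------------------------------
# Deviance and fitting


def _mu_from_eta(eta: np.ndarray) -> np.ndarray:
    return np.clip(1.0 - np.exp(-eta), _MU_EPS, 1.0 - _MU_EPS)


def deviance(d: np.ndarray, mu: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Binomial-type deviance with the 0*ln(0) = 0 convention."""
    d = np.asarray(d, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), _MU_EPS, 1.0 - _MU_EPS)
    w = np.ones_like(d) if weights is None else np.asarray(weights, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(d > 0, d * np.log(d / mu), 0.0)
        t2 = np.where(d < 1, (1.0 - d) * np.log((1.0 - d) / (1.0 - mu)), 0.0)
    return float(2.0 * np.sum(w * (t1 + t2)))


def _null_deviance(d: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Deviance and intercept of the best constant-mu (intercept-only) model."""
    mu_bar = float(np.clip(np.average(d, weights=w), _MU_EPS, 1.0 - _MU_EPS))
    a0 = -np.log1p(-mu_bar)
    return deviance(d, np.full_like(d, mu_bar), w), a0


class GDMConvergenceError(RuntimeError):
    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class GDMModel:
    """Fitted generalized dissimilarity model."""

    intercept: float
    coefs: dict[str, np.ndarray]       # name -> (3,) non-negative
    basis: ISplineBasis
    geo_knots: np.ndarray | None
    D_null: float
    D_fit: float
    n_pairs: int
    method: str = "lbfgs"

    def linear_predictor(self, x_i: dict, x_j: dict, g_ij=None) -> np.ndarray:
        eta = np.asarray(self.intercept, dtype=float)
        for name, a in self.coefs.items():
            if name == GEO:
                if g_ij is None:
                    raise ValueError("model includes geographic distance; g_ij required")
                eta = eta + ISplineBasis.evaluate_knots(self.geo_knots, g_ij) @ a
            else:
                if name not in x_i or name not in x_j:
                    raise KeyError(f"predictor {name!r} missing from inputs")
                di = self.basis.evaluate(name, x_i[name])
                dj = self.basis.evaluate(name, x_j[name])
                eta = eta + np.abs(di - dj) @ a
        return eta

    def predict(self, x_i: dict, x_j: dict, g_ij=None) -> np.ndarray:
        """Predicted dissimilarity mu = 1 - exp(-eta) in [0, 1)."""
        return 1.0 - np.exp(-self.linear_predictor(x_i, x_j, g_ij))

    def fitted(self, pairs: SitePairTable) -> np.ndarray:
        theta = self._theta(pairs)
        return 1.0 - np.exp(-(self.intercept + pairs.X @ theta))

    def _theta(self, pairs: SitePairTable) -> np.ndarray:
        theta = np.zeros(pairs.X.shape[1])
        for name, sl in pairs.blocks.items():
            if name in self.coefs:
                theta[sl] = self.coefs[name]
        return theta

    def to_json(self, path) -> None:
        payload = {
            "intercept": self.intercept,
            "coefs": {k: v.tolist() for k, v in self.coefs.items()},
            "knots": {k: v.tolist() for k, v in self.basis.knots.items()},
            "geo_knots": None if self.geo_knots is None else self.geo_knots.tolist(),
            "D_null": self.D_null,
            "D_fit": self.D_fit,
            "n_pairs": self.n_pairs,
            "method": self.method,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GDMModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            intercept=p["intercept"],
            coefs={k: np.asarray(v) for k, v in p["coefs"].items()},
            basis=ISplineBasis(p["knots"]),
            geo_knots=None if p["geo_knots"] is None else np.asarray(p["geo_knots"]),
            D_null=p["D_null"], D_fit=p["D_fit"], n_pairs=p["n_pairs"],
            method=p.get("method", "lbfgs"),
        )


def _objective(params: np.ndarray, X: np.ndarray, d: np.ndarray, w: np.ndarray):
    eta = params[0] + X @ params[1:]
    mu = _mu_from_eta(eta)
    dev = deviance(d, mu, w)
    # dD/deta = 2 w [ (1-d) - d (1-mu)/mu ]
    g_eta = 2.0 * w * ((1.0 - d) - d * (1.0 - mu) / mu)
    grad = np.empty_like(params)
    grad[0] = g_eta.sum()
    grad[1:] = X.T @ g_eta
    return dev, grad


def _fit_lbfgs(pairs: SitePairTable, max_iter: int) -> np.ndarray:
    m = pairs.X.shape[1]
    _, a0 = _null_deviance(pairs.d, pairs.weights)
    x0 = np.concatenate([[max(a0, 1e-3)], np.full(m, 0.01)])
    res = minimize(
        _objective, x0, args=(pairs.X, pairs.d, pairs.weights), jac=True,
        method="L-BFGS-B", bounds=[(0.0, None)] * (m + 1),
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9, "maxfun": 10 * max_iter},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter reached
        raise GDMConvergenceError(
            f"GDM fit failed to converge: {res.message}",
            {"nit": res.nit, "status": res.status, "fun": res.fun},
        )
    return res.x


def _fit_irls(pairs: SitePairTable, max_iter: int, tol: float = 1e-10) -> np.ndarray:
    """Iteratively reweighted non-negative least squares (GLM working
    response for the 1 - exp(-eta) link, binomial variance)."""
    X1 = np.column_stack([np.ones(pairs.n_pairs), pairs.X])
    d, w = pairs.d, pairs.weights
    _, a0 = _null_deviance(d, w)
    theta = np.concatenate([[max(a0, 1e-3)], np.zeros(pairs.X.shape[1])])
    dev_prev = np.inf
    for _ in range(max_iter):
        eta = X1 @ theta
        mu = _mu_from_eta(eta)
        # d mu / d eta = 1 - mu; variance mu (1 - mu)
        dmu = 1.0 - mu
        z = eta + (d - mu) / dmu
        wk = w * dmu * dmu / (mu * (1.0 - mu))
        sw = np.sqrt(wk)
        theta, _ = nnls(X1 * sw[:, None], z * sw)
        dev = deviance(d, _mu_from_eta(X1 @ theta), w)
        if abs(dev_prev - dev) < tol * (1.0 + abs(dev)):
            break
        dev_prev = dev
    else:
        raise GDMConvergenceError(
            "IRLS/NNLS did not converge", {"max_iter": max_iter, "deviance": dev_prev}
        )
    return theta


def fit(pairs: SitePairTable, method: str = "lbfgs", max_iter: int = 2000,
        min_pairs: int = 30) -> GDMModel:
    """Fit a GDM by minimizing the constrained deviance; deterministic given
    the data.  ``method`` is ``"lbfgs"`` (bound-constrained quasi-Newton,
    default) or ``"irls"`` (iteratively reweighted NNLS)."""
    if pairs.n_pairs < min_pairs:
        raise ValueError(f"need at least {min_pairs} site pairs, got {pairs.n_pairs}")
    if method == "lbfgs":
        theta = _fit_lbfgs(pairs, max_iter)
    elif method == "irls":
        theta = _fit_irls(pairs, max_iter)
    else:
        raise ValueError(f"unknown fit method {method!r}")
    D_null, _ = _null_deviance(pairs.d, pairs.weights)
    mu = _mu_from_eta(theta[0] + pairs.X @ theta[1:])
    D_fit = deviance(pairs.d, mu, pairs.weights)
    coefs = {name: theta[1:][sl].copy() for name, sl in pairs.blocks.items()}
    assert theta.min() >= 0.0, "non-negativity constraint violated"
    return GDMModel(
        intercept=float(theta[0]), coefs=coefs, basis=pairs.basis,
        geo_knots=pairs.geo_knots, D_null=D_null, D_fit=min(D_fit, D_null),
        n_pairs=pairs.n_pairs, method=method,
    )


def deviance_explained(model: GDMModel) -> float:
    """Percent of null deviance explained, in [0, 100]."""
    if model.D_null <= 1e-12:
        raise ValueError("null deviance is (numerically) zero; "
                         "deviance explained undefined")
    return float(100.0 * (model.D_null - model.D_fit) / model.D_null)


def variable_importance(pairs: SitePairTable, full: GDMModel,
                        method: str = "lbfgs") -> pd.DataFrame:
    """Leave-one-out deviance importance of each environmental predictor.

    Geographic distance is retained in every partial model.  Returns a table
    with columns ``predictor``, ``delta_deviance`` and ``percent`` (of the
    full model's explained deviance), sorted descending.
    """
    explained = full.D_null - full.D_fit
    rows = []
    for name in pairs.blocks:
        if name == GEO:
            continue
        sub = pairs.drop_predictor(name)
        try:
            partial = fit(sub, method=method)
            ddev = max(partial.D_fit - full.D_fit, 0.0)
            pct = 100.0 * ddev / explained if explained > 0 else np.nan
            rows.append({"predictor": name, "delta_deviance": ddev, "percent": pct,
                         "converged": True})
        except GDMConvergenceError:
            rows.append({"predictor": name, "delta_deviance": np.nan, "percent": np.nan,
                         "converged": False})
    return (
        pd.DataFrame(rows)
        .sort_values("delta_deviance", ascending=False, na_position="last")
        .reset_index(drop=True)
    )


def transform_grid(model: GDMModel, stack: PredictorStack,
                   chunk_size: int = 200_000, cell_cap: int = 4000) -> np.ndarray:
    """Predicted dissimilarity between every pair of valid grid cells.

    Returns the condensed upper-triangle vector (length G(G-1)/2 for G
    valid cells, scipy pair ordering), computed in chunks of pairs.  Cell
    counts above ``cell_cap`` raise, instructing subsampling.
    """
    cells = stack.cell_table()
    G = len(cells)
    if G > cell_cap:
        raise ValueError(
            f"{G} valid cells exceed the cap of {cell_cap}; subsample the grid "
            "or raise cell_cap"
        )
    if G < 2:
        raise ValueError("need at least 2 valid cells")
    env_names = [n for n in model.coefs if n != GEO]
    missing = [n for n in env_names if n not in stack.layers]
    if missing:
        raise KeyError(f"stack lacks model predictors: {missing}")
    T = np.concatenate(
        [model.basis.evaluate(n, cells[n].to_numpy()) for n in env_names], axis=1
    )
    coef_env = np.concatenate([model.coefs[n] for n in env_names])
    lon = cells["lon"].to_numpy()
    lat = cells["lat"].to_numpy()
    ii, jj = np.triu_indices(G, k=1)
    out = np.empty(ii.shape[0])
    for start in range(0, ii.shape[0], chunk_size):
        sl = slice(start, min(start + chunk_size, ii.shape[0]))
        i, j = ii[sl], jj[sl]
        eta = model.intercept + np.abs(T[i] - T[j]) @ coef_env
        if GEO in model.coefs:
            g = haversine_km(lon[i], lat[i], lon[j], lat[j])
            eta = eta + ISplineBasis.evaluate_knots(model.geo_knots, g) @ model.coefs[GEO]
        out[sl] = 1.0 - np.exp(-eta)
    return out
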