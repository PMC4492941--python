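"""End-to-end bioregionalisation pipeline.

Orchestrates the full analysis from a configuration file: synthetic (or
loaded) data -> predictor extraction -> turnover dissimilarity -> GDM fit
and variable importance -> grid-wide predicted dissimilarity -> NMDS of
observed and predicted matrices -> ordination color and slope maps ->
fuzzy C-means regions with environmental profiles -> indicator species.
Every artifact is written to the output directory and a manifest records
parameters, derived seeds, per-stage wall time, summary statistics and
SHA-256 checksums of all outputs.

One master seed fans out to per-stage seeds by fixed offsets, so a rerun
with the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import squareform

from . import bioregions, gdm, indicators, ordination, predictors, synthetic, turnover
from .containers import (
    PREDICTOR_NAMES,
    GridSpec,
    OccurrenceMatrix,
    PredictorStack,
    read_ascii_grid,
    write_ascii_grid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig", "GDMConfig", "NMDSConfig", "FCMConfig",
    "IndicatorConfig", "PipelineConfig", "run_pipeline",
    "load_config", "save_config", "load_predictor_stack",
]

# master-seed fan-out offsets, one per stochastic stage
_SEED_OFFSETS = {
    "environment": 0,
    "species_pool": 1,
    "occurrences": 2,
    "nmds_observed": 3,
    "nmds_predicted": 4,
    "nmds_subsample": 5,
    "fcm": 6,
    "permutation": 7,
}


@dataclass
class SyntheticConfig:
    n_rows: int = 40
    n_cols: int = 40
    lon_min: float = 10.0
    lon_max: float = 12.0
    lat_min: float = 34.0
    lat_max: float = 36.0
    n_sites: int = 300
    n_species: int = 60
    n_archetypes: int = 3

    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.lon_min, self.lon_max,
                        self.lat_min, self.lat_max)


@dataclass
class GDMConfig:
    method: str = "lbfgs"
    cell_cap: int = 4000
    chunk_size: int = 200_000


@dataclass
class NMDSConfig:
    n_dim: int = 2
    n_starts: int = 100
    max_iter: int = 300
    tol: float = 1e-7
    # grids with more valid cells than this are embedded via a random
    # subsample; remaining cells take their nearest environmental
    # neighbor's coordinates
    cell_cap: int = 3000


@dataclass
class FCMConfig:
    k: int = 3
    m: float = 2.0
    n_init: int = 20
    max_iter: int = 300
    tol: float = 1e-9


@dataclass
class IndicatorConfig:
    stat_threshold: float = 0.6
    p_threshold: float = 0.001
    n_perm: int = 9999
    p_inclusive: bool = False
    stat_form: str = "sqrt"


@dataclass
class PipelineConfig:
    """Full pipeline configuration.

    Defaults are the method's reference operating settings: 2-D NMDS with
    100 random starts, FCM with k=3 and m=2, indicator selection at
    IndVal^g > 0.6 with p < 0.001 from 9999 permutations."""

    seed: int = 0
    outdir: str = "results"
    # either synthetic generation ...
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # ... or paths to real inputs (occurrence CSV + directory of .asc layers)
    occurrences_csv: str | None = None
    predictors_dir: str | None = None
    gdm: GDMConfig = field(default_factory=GDMConfig)
    nmds: NMDSConfig = field(default_factory=NMDSConfig)
    fcm: FCMConfig = field(default_factory=FCMConfig)
    indicators: IndicatorConfig = field(default_factory=IndicatorConfig)

    def __post_init__(self) -> None:
        # re-validate module parameter constraints at load time
        if self.fcm.m <= 1:
            raise ValueError("FCM fuzziness m must exceed 1")
        if self.fcm.k < 2:
            raise ValueError("FCM needs k >= 2 regions")
        if self.nmds.n_dim < 1 or self.nmds.n_starts < 1:
            raise ValueError("NMDS needs n_dim >= 1 and n_starts >= 1")
        if self.indicators.n_perm < 1:
            raise ValueError("indicator permutation count must be >= 1")
        if not (0 <= self.indicators.p_threshold <= 1):
            raise ValueError("p threshold must be a probability")
        self.synthetic.grid()  # raises on invalid grid bounds


def _as_config(cls, value):
    return value if isinstance(value, cls) else cls(**value)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key, cls in [("synthetic", SyntheticConfig), ("gdm", GDMConfig),
                     ("nmds", NMDSConfig), ("fcm", FCMConfig),
                     ("indicators", IndicatorConfig)]:
        if key in raw:
            raw[key] = _as_config(cls, raw[key])
    return PipelineConfig(**raw)


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


def load_predictor_stack(directory) -> PredictorStack:
    """Read the nine named predictor layers (<name>.asc) from a directory."""
    directory = Path(directory)
    grid = None
    layers = {}
    for name in PREDICTOR_NAMES:
        g, arr = read_ascii_grid(directory / f"{name}.asc")
        if grid is None:
            grid = g
        elif g != grid:
            raise ValueError(f"layer {name!r} is not co-registered with the stack")
        layers[name] = arr
    return PredictorStack(grid=grid, layers=layers)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _embed_cells(condensed: np.ndarray, cells: pd.DataFrame, cfg: NMDSConfig,
                 seed_embed: int, seed_sub: int) -> tuple[np.ndarray, float, int]:
    """NMDS coordinates for every grid cell.

    Full NMDS up to ``cfg.cell_cap`` cells; above that, NMDS on a random
    subsample with remaining cells placed at their nearest environmental
    neighbor's coordinates (features standardized per predictor).
    Returns (coords, stress, n_embedded).
    """
    G = len(cells)
    D = squareform(condensed)
    feat = cells[[c for c in cells.columns if c not in ("row", "col", "lon", "lat")]]
    if G <= cfg.cell_cap:
        ordn = ordination.nmds(D, n_dim=cfg.n_dim, n_starts=cfg.n_starts,
                               max_iter=cfg.max_iter, tol=cfg.tol, seed=seed_embed)
        return ordn.coords, ordn.stress, G
    rng = np.random.default_rng(seed_sub)
    sub = np.sort(rng.choice(G, size=cfg.cell_cap, replace=False))
    ordn = ordination.nmds(D[np.ix_(sub, sub)], n_dim=cfg.n_dim,
                           n_starts=cfg.n_starts, max_iter=cfg.max_iter,
                           tol=cfg.tol, seed=seed_embed)
    rest = np.setdiff1d(np.arange(G), sub)
    coords = np.empty((G, cfg.n_dim))
    coords[sub] = ordn.coords
    feats = feat.to_numpy(dtype=float)
    coords[rest] = ordination.place_by_nearest(ordn.coords, feats[sub], feats[rest])
    return coords, ordn.stress, cfg.cell_cap


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest (also written to
    ``<outdir>/manifest.json``).  Any stage failure raises with the stage
    name; artifacts of completed stages are preserved on disk."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {k: cfg.seed + v for k, v in _SEED_OFFSETS.items()}
    manifest: dict = {
        "config": dataclasses.asdict(cfg),
        "seeds": seeds,
        "stages": {},
        "summary": {},
        "outputs": {},
    }
    timings = manifest["stages"]
    summary = manifest["summary"]
    written: list[Path] = []

    def stage(name):
        logger.info("stage %s", name)
        return _StageTimer(name, timings)

    def write_layer(name: str, grid: GridSpec, arr: np.ndarray, sub: str = ""):
        d = out / sub if sub else out
        d.mkdir(parents=True, exist_ok=True)
        p = d / f"{name}.asc"
        write_ascii_grid(p, grid, arr)
        written.append(p)

    def write_csv(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)

    # ---- data ------------------------------------------------------------
    truth_labels = None
    with stage("data"):
        if cfg.occurrences_csv is not None:
            if cfg.predictors_dir is None:
                raise ValueError("predictors_dir is required with occurrences_csv")
            occ = OccurrenceMatrix.from_csv(cfg.occurrences_csv)
            env = load_predictor_stack(cfg.predictors_dir)
        else:
            grid = cfg.synthetic.grid()
            env = synthetic.generate_environment(grid, seed=seeds["environment"])
            pool, truth = synthetic.generate_species_pool(
                cfg.synthetic.n_species, cfg.synthetic.n_archetypes,
                seed=seeds["species_pool"], env=env)
            occ = synthetic.sample_occurrences(pool, env, cfg.synthetic.n_sites,
                                               seed=seeds["occurrences"])
            truth.region_labels = synthetic.true_regions(pool, env)
            truth_labels = truth.region_labels
            write_csv(truth.labels_frame(grid), "true_regions.csv")
            write_csv(pd.DataFrame({
                "species": [sp.name for sp in pool.species],
                "archetype": truth.archetype_of_species,
            }), "species_archetypes.csv")
        occ.to_csv(out / "occurrences.csv")
        written.append(out / "occurrences.csv")
        for name, arr in env.layers.items():
            write_layer(name, env.grid, arr, sub="predictors")
        summary["n_sites"] = occ.n_sites
        summary["n_species"] = occ.n_species
        summary["mean_prevalence"] = float(occ.prevalence().mean())

    # ---- predictors at sites ---------------------------------------------
    with stage("predictors"):
        sites = pd.DataFrame({"site_id": occ.site_id, "lon": occ.lon, "lat": occ.lat})
        site_table = predictors.extract_at_sites(env, sites)
        if len(site_table) != occ.n_sites:
            raise ValueError("sites were dropped during extraction; "
                             "occurrence matrix and site table are out of step")
        geo = predictors.geographic_distance(site_table["lon"].to_numpy(),
                                             site_table["lat"].to_numpy())
        write_csv(site_table, "sites.csv")

    # ---- turnover ---------------------------------------------------------
    with stage("turnover"):
        turn = turnover.turnover_matrix(occ)
        df = pd.DataFrame(turn, columns=[str(s) for s in occ.site_id])
        df.insert(0, "site_id", occ.site_id)
        write_csv(df, "observed_turnover.csv")
        summary["mean_observed_turnover"] = float(
            turnover.condensed(turn).mean())

    # ---- GDM ---------------------------------------------------------------
    with stage("gdm"):
        pairs = gdm.build_site_pairs(occ, site_table, turn, geo)
        model = gdm.fit(pairs, method=cfg.gdm.method)
        model.to_json(out / "gdm_model.json")
        written.append(out / "gdm_model.json")
        summary["deviance_explained_pct"] = gdm.deviance_explained(model)
        imp = gdm.variable_importance(pairs, model, method=cfg.gdm.method)
        write_csv(imp, "variable_importance.csv")
        summary["top_predictor"] = str(imp.iloc[0]["predictor"])

    # ---- grid transform ----------------------------------------------------
    with stage("transform"):
        mu = gdm.transform_grid(model, env, chunk_size=cfg.gdm.chunk_size,
                                cell_cap=cfg.gdm.cell_cap)
        cells = env.cell_table()
        summary["n_grid_cells"] = len(cells)

    # ---- ordination --------------------------------------------------------
    with stage("ordination"):
        obs_ord = ordination.nmds(turn, n_dim=cfg.nmds.n_dim,
                                  n_starts=cfg.nmds.n_starts,
                                  max_iter=cfg.nmds.max_iter, tol=cfg.nmds.tol,
                                  seed=seeds["nmds_observed"])
        summary["stress_observed"] = obs_ord.stress
        coords, stress_pred, n_embedded = _embed_cells(
            mu, cells, cfg.nmds, seeds["nmds_predicted"], seeds["nmds_subsample"])
        summary["stress_predicted"] = stress_pred
        summary["n_cells_embedded"] = n_embedded
        obs_df = pd.DataFrame({"site_id": occ.site_id,
                               "axis1": obs_ord.coords[:, 0],
                               "axis2": obs_ord.coords[:, 1]})
        write_csv(obs_df, "nmds_observed.csv")
        pred_df = cells[["row", "col", "lon", "lat"]].copy()
        pred_df["axis1"] = coords[:, 0]
        pred_df["axis2"] = coords[:, 1]
        write_csv(pred_df, "nmds_predicted.csv")

    # ---- colors and slope map ---------------------------------------------
    with stage("maps"):
        colors = ordination.coords_to_colors(coords)
        grid_shape = (env.grid.n_rows, env.grid.n_cols)
        rows = cells["row"].to_numpy()
        cols = cells["col"].to_numpy()
        coord_layers = np.full((2,) + grid_shape, np.nan)
        for k in range(2):
            coord_layers[k, rows, cols] = coords[:, k]
        for k, channel in enumerate("rgb"):
            layer = np.full(grid_shape, np.nan)
            layer[rows, cols] = colors[:, k]
            write_layer(f"color_{channel}", env.grid, layer, sub="maps")
        slope_map = ordination.turnover_slope_map(coord_layers, env.grid)
        write_layer("beta_slope", env.grid, slope_map, sub="maps")

    # ---- fuzzy regions -----------------------------------------------------
    with stage("regions"):
        part = bioregions.fuzzy_cmeans(coords, k=cfg.fcm.k, m=cfg.fcm.m,
                                       tol=cfg.fcm.tol, max_iter=cfg.fcm.max_iter,
                                       n_init=cfg.fcm.n_init, seed=seeds["fcm"])
        labels = bioregions.hard_assignment(part)
        for r in range(part.k):
            layer = np.full(grid_shape, np.nan)
            layer[rows, cols] = part.memberships[:, r]
            write_layer(f"membership_{r}", env.grid, layer, sub="regions")
        label_layer = np.full(grid_shape, np.nan)
        label_layer[rows, cols] = labels
        write_layer("hard_labels", env.grid, label_layer, sub="regions")
        write_csv(pd.DataFrame(bioregions.region_colors(part),
                               columns=["r", "g", "b"]), "region_colors.csv")
        env_cols = [c for c in cells.columns if c not in ("row", "col", "lon", "lat")]
        profiles = bioregions.radial_profile(part, cells[env_cols])
        write_csv(profiles, "region_profiles.csv")
        summary["region_sizes"] = np.bincount(labels, minlength=part.k).tolist()
        if truth_labels is not None:
            from sklearn.metrics import adjusted_rand_score

            tl = truth_labels[np.isfinite(truth_labels)].astype(int)
            summary["ari_vs_truth"] = float(adjusted_rand_score(tl, labels))

    # ---- indicator species -------------------------------------------------
    with stage("indicators"):
        srow, scol = env.grid.nearest_cell(occ.lon, occ.lat)
        cell_index = np.full(grid_shape, -1, dtype=int)
        cell_index[rows, cols] = np.arange(len(cells))
        site_labels = labels[cell_index[srow, scol]]
        results, selected = indicators.indicator_analysis(
            occ, site_labels, n_perm=cfg.indicators.n_perm,
            seed=seeds["permutation"], stat_form=cfg.indicators.stat_form,
            stat_threshold=cfg.indicators.stat_threshold,
            p_threshold=cfg.indicators.p_threshold,
            p_inclusive=cfg.indicators.p_inclusive)
        write_csv(results, "indicator_results.csv")
        write_csv(selected, "indicator_species.csv")
        summary["n_indicator_species"] = int(len(selected))
        summary["indicators_per_region"] = {
            int(r): int(n) for r, n in
            selected.groupby("region").size().items()
        }

    manifest["outputs"] = {str(p.relative_to(out)): _sha256(p) for p in sorted(written)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


class _StageTimer:
    def __init__(self, name: str, sink: dict):
        self.name = name
        self.sink = sink

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.sink[self.name] = {"seconds": round(time.perf_counter() - self.t0, 3)}
        if exc is not None:
            self.sink[self.name]["failed"] = repr(exc)
            logger.error("stage %s failed: %r", self.name, exc)
        return False
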