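"""Shared fixtures: small synthetic inputs and one desk-scale pipeline run.

The full pipeline run is session-scoped and shared by the pipeline and
acceptance tests so the most expensive stage (grid NMDS) happens once.
"""

import warnings

import numpy as np
import pytest

from betaregio import (
    NMDSConfig,
    PipelineConfig,
    SyntheticConfig,
    run_pipeline,
    synthetic,
)


@pytest.fixture(scope="session")
def default_env():
    """Default synthetic seascape environment (40x40 grid, seed 0)."""
    return synthetic.generate_environment(seed=0)


@pytest.fixture(scope="session")
def default_survey(default_env):
    """Species pool, truth and a 300-site survey on the default seascape."""
    pool, truth = synthetic.generate_species_pool(60, 3, seed=1, env=default_env)
    occ = synthetic.sample_occurrences(pool, default_env, 300, seed=2)
    truth.region_labels = synthetic.true_regions(pool, default_env)
    return pool, truth, occ


#: desk-scale analysis options: NMDS on a 700-cell subsample with 4 starts
#: (remaining cells placed at their nearest environmental neighbor)
def desk_config(seed: int, outdir: str) -> PipelineConfig:
    return PipelineConfig(
        seed=seed,
        outdir=outdir,
        synthetic=SyntheticConfig(),  # 40x40 grid, 300 sites, 60 species, 3 archetypes
        nmds=NMDSConfig(n_starts=4, cell_cap=700, max_iter=150, tol=1e-6),
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run on the default synthetic seascape (seed 1)."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = desk_config(seed=1, outdir=str(outdir))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = run_pipeline(cfg)
    return cfg, manifest, outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
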