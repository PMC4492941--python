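"""Model species turnover with a generalized dissimilarity model.

Computes pairwise beta_jtu among survey sites, fits the GDM (nine
spline-transformed environmental predictors + geographic distance,
non-negative coefficients, 1 - exp(-eta) link), and prints the deviance
explained and the drop-one variable importance table.
"""

import warnings

import pandas as pd

from betaregio import gdm, predictors, synthetic, turnover

warnings.filterwarnings("ignore")

env = synthetic.generate_environment(seed=0)
pool, truth = synthetic.generate_species_pool(60, 3, seed=1, env=env)
occ = synthetic.sample_occurrences(pool, env, 300, seed=2)

turn = turnover.turnover_matrix(occ)
sites = pd.DataFrame({"site_id": occ.site_id, "lon": occ.lon, "lat": occ.lat})
site_table = predictors.extract_at_sites(env, sites)
geo = predictors.geographic_distance(occ.lon, occ.lat)

pairs = gdm.build_site_pairs(occ, site_table, turn, geo)
model = gdm.fit(pairs)

print(f"site pairs: {pairs.n_pairs}")
print(f"mean observed beta_jtu: {turnover.condensed(turn).mean():.3f}")
print(f"deviance explained: {gdm.deviance_explained(model):.1f}%")
print()
print("variable importance (deviance change when removed, % of explained):")
imp = gdm.variable_importance(pairs, model)
print(imp.to_string(index=False,
                    formatters={"delta_deviance": "{:.1f}".format,
                                "percent": "{:.1f}".format}))
print()
print("Depth dominates (the shelf break is the strongest compositional")
print("boundary), with the front variables (SST/SSS) next; a high deviance")
print("explained means pairwise turnover is predictable from environment.")
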