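# betaregio

Beta-diversity turnover modeling and fuzzy bioregionalisation for marine
species assemblages.

## The problem

Marine spatial management needs objective region boundaries, but survey
data are sparse: presence/absence records exist only at trawled sites,
while managers need wall-to-wall maps. `betaregio` implements the
standard modeling chain that bridges that gap for demersal shelf-sea
communities:

1. **Turnover dissimilarity.** Compositional difference between two
   sites is measured by the turnover component of Jaccard dissimilarity,

   β<sub>jtu</sub> = 2·min(B, C) / (A + 2·min(B, C)),

   where A is the number of shared species and B, C the numbers unique
   to each site. Turnover isolates species *replacement*: nested
   assemblages score 0 regardless of richness differences, and joint
   absences never contribute.

2. **Generalized dissimilarity model (GDM).** Pairwise turnover is
   regressed on environmental differences and geographic distance via

   η<sub>ij</sub> = a₀ + Σ<sub>p</sub> Σ<sub>k</sub> a<sub>pk</sub> |I<sub>pk</sub>(x<sub>ip</sub>) − I<sub>pk</sub>(x<sub>jp</sub>)|,  μ<sub>ij</sub> = 1 − exp(−η<sub>ij</sub>),

   with three monotone I-spline basis functions per predictor (knots at
   the 0/50/100th percentiles) and coefficients constrained ≥ 0, fitted
   by minimizing the binomial-type deviance. Nine predictors are used —
   SST mean/range, SSS mean/range, bathymetry, slope, eastness,
   northness, distance to shore — plus great-circle distance between
   sites. Predictor importance is the deviance increase when a variable
   is refitted out of the model.

3. **Grid-wide prediction and ordination.** The fitted model predicts
   dissimilarity between every pair of raster cells; 2-D nonmetric
   multidimensional scaling (NMDS, Kruskal stress-1, best of many random
   starts) embeds that matrix, positions become RGB colors (similar
   color = similar predicted assemblage), and the spatial gradient
   magnitude of the ordination axes maps the "slope" of beta diversity.

4. **Fuzzy bioregions.** Fuzzy C-means (k = 3, fuzziness m = 2) on the
   ordination coordinates yields graded region memberships; regions are
   profiled by membership-weighted environmental means.

5. **Indicator species.** Each species gets the group-equalized
   indicator value IndVal<sup>g</sup> = √(A·B) (specificity × fidelity on
   within-group frequencies), a 9999-permutation p-value, and species
   with IndVal<sup>g</sup> > 0.6 and p < 0.001 characterize each region.

A synthetic seascape generator (coastline, wide southern shelf with a
sharp break, an oceanographic front, archetype-structured species pool)
provides ground truth for every stage.

## Worked example

`examples/02_turnover_and_gdm.py` builds the default synthetic survey
(300 sites × 60 species), computes all 44 850 pairwise β<sub>jtu</sub>
values and fits the GDM:

```
site pairs: 44850
mean observed beta_jtu: 0.739
deviance explained: 78.4%

variable importance (deviance change when removed, % of explained):
 predictor delta_deviance percent  converged
bathymetry         4614.4    26.1       True
  sss_mean           74.1     0.4       True
 sst_range           61.1     0.3       True
...
```

Depth dominates because the shelf break is the sharpest compositional
boundary in the generated seascape; the salinity/temperature front
variables follow. `examples/03_ordination_and_regions.py` then embeds
the turnover matrix (stress 0.084), clusters it into three fuzzy regions
and prints their environmental profiles — one deep (mean depth 847 m),
one warm and salty (22.4 °C, 37.8 psu), one cooler northern shelf
region. `examples/05_full_pipeline.py` runs everything end to end and
reports, among other numbers, the adjusted agreement between recovered
regions and the generator's truth.

The same pipeline runs from the shell:

```bash
betaregio init-config config.yaml   # defaults: 100 NMDS starts, 9999 perms
betaregio run -c config.yaml
```

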