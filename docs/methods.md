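# Methods

This note documents the models, numerical choices and known limitations
of `betaregio`. Notation: sites i, j; species counts A (shared), B, C
(unique); predictors p with per-site values x<sub>ip</sub>.

## Turnover dissimilarity

β<sub>jtu</sub> = 2·min(B,C) / (A + 2·min(B,C)) is computed exactly from
integer co-occurrence counts, vectorized as X·Xᵀ on the 0/1 site-by-
species matrix. Properties relied on downstream: joint-absence
invariance, zero turnover for nested pairs, and values in [0, 1].

*Degenerate input.* If A + 2·min(B,C) = 0 (at least one empty
assemblage), turnover is defined as 0 with a warning — no species
replaces another — and empty sites are excluded from GDM fitting, where
they would otherwise contribute pure-convention responses.

## Generalized dissimilarity model

- **Transforms.** Each predictor gets three order-2 (quadratic)
  I-splines with knots at the 0th/50th/100th percentiles of its observed
  site values, built as reversed cumulative sums of a degree-2 B-spline
  basis; each basis function rises monotonically from 0 (predictor
  minimum) to 1 (maximum), and evaluation clamps outside the observed
  range. A constant predictor admits no monotone basis and is dropped
  with a warning; a median coinciding with an endpoint is moved to the
  interval midpoint to keep the quadratic basis valid.
- **Geographic distance** enters as a predictor in its own right: the
  spline is evaluated on the pair distance g<sub>ij</sub> (haversine,
  spherical Earth R = 6371 km), with knots from the percentiles of the
  observed pair distances.
- **Link and objective.** μ = 1 − exp(−η) with η ≥ 0 guaranteed by the
  non-negativity of the intercept and coefficients; the fit minimizes
  the binomial-type deviance with the 0·ln 0 := 0 convention and μ
  clamped to [10⁻⁶, 1 − 10⁻⁶] against log singularities. The null
  deviance uses the best constant model, μ̄ = mean(d), whose intercept
  is −ln(1 − μ̄) in closed form.
- **Optimizers.** Default is bound-constrained L-BFGS-B with the
  analytic gradient (∂D/∂η = 2w[(1−d) − d(1−μ)/μ]); an alternative
  iteratively-reweighted NNLS path (GLM working response for this link,
  binomial variance) is provided and the two agree on test fixtures to
  within 0.5 percentage points of deviance explained. Fits are
  deterministic given the data. Pair weights default to 1.
- **Importance.** For each environmental predictor, the model is refitted
  without it (geographic distance is retained in every partial model);
  ΔDev = D_partial − D_full, reported also as a percentage of the full
  model's explained deviance (D_null − D_fit). With correlated
  predictors drop-one ΔDev understates shared contributions — expected
  behavior of this statistic, visible in the examples where the front
  signal is split between SST and SSS.
- **Grid transform.** Predicted dissimilarity is computed for all pairs
  of valid raster cells in chunks of pairs (condensed upper-triangle
  storage); a configurable cell cap (default 4000, ~8M pairs) guards
  memory and instructs subsampling beyond it.

*Degenerate case.* When all observed dissimilarities are equal the null
model is already perfect (D_null = 0) and deviance explained is an
undefined 0/0; `deviance_explained` raises rather than reporting 0.

## Ordination

NMDS minimizes Kruskal stress-1, √(Σ(d̂ − δ)²/Σδ²), where δ are
configuration distances and d̂ the isotonic regression of δ on the input
dissimilarities (pooled adjacent violators; ties in the input are
ordered secondarily by δ). The optimizer is SMACOF: each iteration fits
disparities, rescales them to the configuration's sum of squares for the
Guttman transform, and updates the configuration. An iteration that
fails to decrease stress terminates its start, so recorded stress traces
are non-increasing by construction. The best of n_starts initializations
is returned (random start s is seeded with seed + s); the first start is
warm-started from the classical-scaling (metric MDS) configuration, the
standard practice that both speeds convergence and anchors the nonmetric
solution to the metric geometry — important here because the saturating
dissimilarities leave several low-stress configurations that curl the
dominant gradient differently. Reported stress uses the raw isotonic
fit, the textbook stress-1.

- **Large grids.** Full pairwise NMDS runs up to a configurable cell cap
  (default 3000). Beyond it, NMDS runs on a random subsample and the
  remaining cells are placed at the coordinates of their nearest
  neighbor in standardized predictor space — cells with near-identical
  environments have near-identical predicted assemblages under the GDM,
  so environmental proximity is the right placement rule. A test checks
  the color structure of the subsampled embedding against the full one
  (rank correlation > 0.9).
- **Colors.** Both ordination axes are min-max scaled to [0, 1] and
  mapped to RGB as (axis1, axis2, 1 − (axis1+axis2)/2), clamped; a
  zero-range axis yields the constant 0.5. The rule is arbitrary but
  fixed, which is what reproducible maps need.
- **Slope map.** Per cell, √(Σ_axes (∂axis/∂x)² + (∂axis/∂y)²) by
  central differences with kilometer cell sizes (east-west size scaled
  by cos(latitude)). High values mark sharp compositional transitions.

## Fuzzy regions

Standard fuzzy C-means on the NMDS coordinates: memberships
u<sub>ik</sub> ∝ ‖x−c<sub>k</sub>‖^(−2/(m−1)) (a point coincident with a
centroid takes membership 1 there), centroids are u^m-weighted means,
and the objective J = ΣΣ u<sup>m</sup>‖x−c‖² is asserted non-increasing
every iteration. Defaults are k = 3 — matching the three archetype
regions of the default seascape, and the typical number of management
zones such analyses inform — and m = 2, inside the commonly recommended
1.5–3 range; 20 seeded restarts, best J wins.
Hard labels are argmax memberships with ties broken toward the lowest
region index (logged). Radial profiles report both membership-weighted
min-max-scaled values (comparable on one radial axis) and raw weighted
means.

## Indicator species

For presence/absence data with groups k: f<sub>k</sub> = within-group
occurrence frequency, specificity A<sub>k</sub> = f<sub>k</sub>/Σf,
fidelity B<sub>k</sub> = f<sub>k</sub>, and IndVal<sup>g</sup> =
√(A·B) — the group-equalized form, invariant to duplicating any group's
sites. A `stat_form="product"` switch provides the plain product.
Significance: site labels are permuted (default 9999 times) and
p = (1 + #{perm ≥ obs})/(1 + n_perm) for each species' max-over-regions
statistic. The estimator counts ties, so p-values are valid but
conservative (super-uniform) for binary data. Selection is strict
(stat > 0.6 and p < 0.001) with a `p_inclusive` option for p ≤ threshold.
Note n_perm must exceed 1/p_threshold − 1 for any species to clear a
strict threshold.

## Synthetic seascape

The generator emulates a shelf-sea survey domain rather than any real
coastline: a western land strip; a shelf of near-uniform depth (60 m
+ 0.3 m/km) that is wide in the south (145 km) and narrow in the north
(50 km), dropping through a sharp sigmoid break (5 km width) onto a
900 m plain; and an oceanographic front at 52% of the latitude span
carrying steps of 3 °C (SST) and 0.8 psu (SSS), plus shallow-water
warming terms and smooth Gaussian-field noise. SST/SSS are produced as
12 monthly layers and reduced to annual mean and range by the standard
climatology operation; slope and aspect (eastness/northness) derive
from the bathymetry; distance to shore is great-circle to the nearest
land cell. The sharp break and front matter: bioregions are crisp where
physical boundaries are crisp, and a purely gradual seascape yields
genuinely ambiguous regions that no method can recover cleanly.

Species niches are Gaussian on transformed predictors (log₁₀ depth,
linear SST/SSS) around archetype templates placed at fixed quantiles of
the cell-level predictor distributions — coastal-south (shallow, warm,
salty), coastal-north (shallow, cool), offshore (deep, broad
temperature tolerance). The offshore archetype's depth response
saturates (flat beyond its optimum), reflecting eurybathic deep-water
fauna; without it the deep gradient keeps elongating in composition
space. Per-species parameters jitter around the template; maximum
occurrence probabilities are Beta(6, 1)-distributed. Defaults (40×40
grid at 0.05°, 300 sites, 60 species, 3 archetypes) are calibrated so
mean prevalence lands near 30% of sites with a rare-to-common spread,
matching the survey summaries the generator emulates. True region
labels are the argmax of the archetype template responses per cell.

What the generator does *not* emulate: spatially autocorrelated
sampling effort, temporal dynamics, detection error, species
interactions, or abundance. Tests passing on this seascape show the
pipeline recovers structure that is present and recoverable; they do
not certify performance on surveys whose structure is weaker or
confounded.

## Problem sizes and defaults

Pipeline defaults are the method's reference settings (2-D NMDS with
100 starts; FCM k=3, m=2, 20 restarts; 9999 permutations;
IndVal<sup>g</sup> > 0.6, p < 0.001). The test suite and the acceptance
script run the same
pipeline at desk scale: 4 NMDS starts and a 700-cell embedding subsample
for the ~1460-cell grid (placement by nearest environmental neighbor for
the rest), chosen so a full run completes in about a minute on one CPU
while leaving the recovery results materially unchanged.

## Known limitations

- Drop-one importance divides shared deviance among correlated
  predictors; it ranks, it does not partition.
- The NMDS arch (Guttmann) effect on strongly one-dimensional gradients
  is not diagnosed or corrected.
- No model selection or significance testing for the GDM itself; no
  cross-validation.
- Region recovery on the synthetic seascape varies with the seed
  (adjusted agreement roughly 0.85–0.92 on probed seeds with the
  classical warm start; purely random starts are markedly less stable);
  boundary cells between regions are genuinely ambiguous under fuzzy
  clustering.
- Rasters must share one lon/lat grid; no reprojection. ESRI ASCII grid
  I/O requires square cells in degrees.
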