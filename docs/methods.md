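# Methods

This note documents the models, the numerical conventions, the synthetic
data generator and the design decisions behind `dasypop`.

## Grid and coordinate conventions

The analysis grid is a north-up regular lattice (row 0 at the northern
edge, 0-based indices, half-open cell intervals in projected coordinates).
The nominal resolution is 3 arc-seconds (~100 m at the equator). Two
rasters are *aligned* only if origin, cell size and dimensions are
identical; every operation that combines rasters requires alignment and
raises otherwise.

Two coordinate frames are supported. Geographic data (WGS 84) is the
native frame of real census and settlement products; all metric
computations (unit areas, distance surfaces) conceptually pass through the
region-specific UTM zone, implemented with a transverse-Mercator forward
projection (Krueger series, sub-metre accuracy within a zone). Synthetic
data uses a planar pseudo-projection with exact 100 m cells so that areas
are exact and tests have no projection error term; latitude-dependent cell
area is deliberately out of scope.

Polygons are rasterized by the cell-center rule: a cell belongs to the
unit covering its center, with centers exactly on shared boundaries going
to the lowest unit index. This is deterministic and partition-preserving;
no claim is made that any particular GIS implements the same tie-break.

## Census aggregation

Models are trained on a two-thirds aggregate of the finest census level:
`target_count = floor((1 − fraction)·N)` with `fraction = 1/3`. Units are
drawn uniformly at random — no spatial or size stratification — and each
drawn unit is dissolved into the neighbor sharing the longest border;
draws that hit already-absorbed units are skipped and replaced. The
floor-based target reproduces the printed aggregate counts for all six
reference countries, including the non-divisible ones
(570→380, 17 459→11 639, 12 666→8 444, 36 042→24 028, 9 192→6 128,
7 416→4 944), and the output count is independent of the seed.

Shared-border lengths are computed once from pairwise boundary
intersections and then maintained *additively* through the dissolve
sequence: for a polygon partition, the border a merged unit shares with a
third unit equals the sum of its members' borders, so the additive update
is exactly equivalent to recomputing geometry after every dissolve (the
design choice was sequential dissolves with recomputation, not a
precomputed merge plan). This keeps 36 000-unit national tessellations at
a few seconds instead of hours. Ties on border length break to the
smallest unit id under string ordering. Output geometries are materialized
once at the end as unions of each surviving group; populations and areas
are summed in integer/float arithmetic, so the national total is conserved
exactly.

The Average Spatial Resolution, `ASR = sqrt(total_area / N)` in km, is the
effective linear unit size and is reported for both levels.

## Built-settlement harmonization

Settlement products are binarized (category list or threshold), resampled
to the analysis grid by *presence/non-presence* — a coarse cell is built
iff any native cell with positive-area overlap is built — and optionally
unioned into a combined layer that trades commission for fewer omissions.
Partial-overlap native cells count as covering; the native grid must be at
least as fine as the target.

Distance-to-outer-edge (DTE) surfaces are signed: negative inside built
features, positive outside, magnitude the exact Euclidean distance (in
metres on the projected grid, via distance transform) to the nearest
opposite-class cell. The sign convention preserves interior depth as well
as exterior proximity for the forest; it is this package's convention,
chosen where the workflow leaves it open.

## Covariate stack and analysis mask

All layers are aligned to the grid and clipped to a single analysis mask:
cells inside the country boundary buffered *outward* by 8 km, excluding
water land-cover classes. The outward buffer over-estimates borders on
purpose so that every stacked covariate shares one extent even where
product borders disagree; water exclusion keeps population off
hydrofeatures. After assembly the nodata footprint is identical across all
layers (a cell missing in any layer is masked everywhere). Zonal
statistics (mean/sum/count) are computed by grouped accumulation; zonal
sums are conservative to float precision, and units with zero valid cells
are flagged rather than silently dropped.

## Models

All three models share the redistribution core
`p_ij = P_i · w′_ij / Σ_j w′_ij` with `w′ = w · b` under a built
constraint `b`; per-unit sums match census counts to better than 1e-6
relative (float64 arithmetic, one division per unit).

* **Model 1** (binary dasymetric): `w = 1`, `b` = settlement mask.
* **Model 2** (forest + dasymetric): `w = exp(ŷ)` from the forest, no
  constraint.
* **Model 3** (hybrid): identical `w` to model 2 — the same predicted
  surface object can be passed to both — masked by `b`.

The regression forest uses 500 trees (stable out-of-bag error),
`mtry = max(1, floor(p/3))` and a minimum terminal-node size of 5 —
standard regression-forest defaults, since only the tree count is pinned
by the reference procedure. The response is log density
`log(P_i/A_i)` per aggregated unit; zero-population units stay in training
via a `log((P_i + 0.5)/A_i)` pseudo-count and are listed on the model
object. Out-of-bag variance explained (R² × 100) and per-predictor
permutation importance (mean MSE increase over 5 permutations) are
exported for reporting. Pixel predictions use the pixel's own covariate
values (not zonal means) and are exponentiated, so weights are strictly
positive; no area normalization is needed because redistribution
renormalizes within units.

**Empty units.** A unit whose constrained weights sum to zero would lose
its population; instead a three-pass widening fallback applies: (1) built
cells within the unit (the normal path when any exist); (2) cells of the
unit within a one-cell (3×3) dilation of the built mask; (3) uniform over
all valid cells of the unit. The pass used is logged per unit and carried
into output metadata. The widening rule is this package's concretization
of the iterative reallocation the reference procedure alludes to but does
not specify.

## Validation

Outputs are scored against the withheld finest level by summing pixels
within each finest unit: RMSE, %RMSE, MAE, and density RMSE/MAE on
people/km² (UTM-projected areas). %RMSE is normalized by the mean observed
count; the normalizer and density units are recorded in the report
metadata because the reference tables leave both conventions unstated, so
alternates can be derived from the per-unit rows. Finest units claiming no
grid cell are excluded and listed. `compare_models` ranks configurations
by RMSE and flags per-metric minima.

## Synthetic countries

The generator emulates the input data at desk scale so that every stage
runs with no external data, with all randomness from a single seed:

* **Settlement truth** — Poisson-placed Gaussian clusters thresholded to
  binary. Most clusters are villages (σ ∈ [0.6, 1.4] cells, amplitude
  [0.55, 1.1]); a 3% fraction are towns (σ ∈ [2.5, 4], amplitude
  [1.5, 3]). 2.5 clusters per unit put settlement in ≈ 90% of units. The
  urban tail matters: it spreads training units across the rural-to-urban
  density range, which is what lets pixel-level forest predictions
  differentiate within built areas (without it the forest weight surface
  is nearly constant inside settlement and the hybrid collapses onto the
  binary dasymetric model).
* **Mask variants** — whole-cluster omissions, scattered single-cell
  commissions, and regeneration on an integer-factor finer native grid
  (WSF-like: 15%/3%/×3; GHSL-like: 25%/6%/×2; HRSL-like: 5%/1%/×4),
  resampled back by presence/non-presence, plus their union (COMBO).
* **Covariates** — signed DTE of each variant; a lights layer
  `1.2·settlement_field + 1.5·exp(−DTE⁺/400 m)` plus smooth and white
  noise (brightness grows with settlement intensity and proximity); a
  smooth climate-like field; two decoy noise layers.
* **Density** — `log λ = β₀ − 4.0·DTE_km + 1.0·lights + ε`, with ε a
  σ = 0.15 smoothed Gaussian field and β₀ calibrated so the expected total
  is `mean_unit_pop × n_units` (default 150 per unit). The defaults place
  ~95% of expected mass inside built cells — the premise under which
  settlement-constrained models are sensible — and put the forest's
  out-of-bag variance explained at ~75–80% for a 570-unit country,
  matching the regime reported for real national runs, and ~25–65% for
  60-unit toys.
* **Census counts** — Poisson draws of per-unit Σλ: integer, non-negative,
  realistic count noise. Per-unit populations therefore equal the zonal
  sums of the true density only in expectation.
* **Tessellation** — rows-of-rectangles partition snapped to cell edges,
  valid for any unit count; lakes that would swallow a unit whole are
  drained so every unit keeps a valid cell.

What the generator does *not* emulate: real settlement-classifier spatial
error structure (only omission/commission/resolution), anisotropic
geography (roads, coasts), latitude-dependent cell areas, and census
undercount. Passing tests on synthetic data therefore demonstrate the
correctness and statistical behaviour of the pipeline, not the accuracy of
any real national map.

## Problem sizes and determinism

Test and reference computations use desk-scale problems chosen to keep the
full suite at a couple of minutes: 60–100-unit countries on 60–100² grids
for model comparisons (20 seeded replicates), a 570-unit country on a 200²
grid for the forest-regime check, and bare tessellations (no rasters) up
to 36 042 units for the aggregation count contract. All stochastic steps
take explicit integer seeds (numpy `default_rng`, scikit-learn
`random_state`); re-running any step with the same seed reproduces the
output bit-for-bit, and the pipeline manifest records the config digest so
unchanged runs are reused.

## Known limitations

* GeoJSON is the only vector format (no Shapefile driver dependency);
  rasters are single-band GeoTIFFs with the grid definition carried in the
  ImageDescription tag alongside standard pixel-scale/tiepoint tags.
* Geographic-CRS support covers single-country extents in one UTM zone;
  no global mosaics or tiled pyramids.
* The permutation importance is computed on the training sample, not out
  of bag; rankings are reliable, absolute values are optimistic.
* `compare_models` requires reports scored on the same unit set; there is
  no cross-country normalization.
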