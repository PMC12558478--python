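# Methods

This note documents the models, parameters and numerical choices behind
`facdamage`: what each pipeline stage computes, what the synthetic-city
generator does and does not emulate, and where genuinely open design
decisions were resolved.

## Problem setting

Post-earthquake building-damage models come in two output dialects. A
segmentation-style model emits building footprint *polygons*, each carrying
the fraction of footprint pixels labelled damaged; a classification-style
model emits building *centroid points*, each carrying a binary damage class
(major damage/destroyed vs not). Neither speaks about health facilities.
The pipeline's job is to convert either dialect, plus a list of geocoded
facility points, into per-facility damaged/undamaged calls, and to quantify
agreement between dialects and accuracy against gold-standard labels.

## Coordinate handling

Every distance and area rule in the pipeline is metric ("25 meters",
"0.125 km²"), so all spatial logic runs in planar meters. Geographic inputs
are projected with a transverse Mercator on the WGS84 ellipsoid whose
central meridian sits at the data centroid — a per-city "local UTM". Within
~50 km of the central meridian the series truncation error is below a
millimeter, far inside geocoding noise. The projection is implemented
directly (standard Snyder series, forward and inverse) and verified in the
test suite against an independent Vincenty geodesic oracle; round-trips are
accurate to < 1e-6°. Facility files that already carry projected `x`/`y`
columns are trusted as-is so that companion building files written in the
same frame stay aligned.

GeoPackage input is handled by a minimal read-only reader: a GeoPackage is
an SQLite database whose geometry blobs are WKB behind a short binary
header, which the standard library plus shapely cover without a GDAL stack.

## Decision rules and thresholds

| parameter | default | units | role |
|---|---|---|---|
| `polygon_damage_cut` | 0.40 | fraction | building damaged iff fraction **>** cut (strict) |
| `rescue_radius_m` | 25 | m | facility within (strict) radius of a damaged centroid is damaged |
| `cell_area_km2` | 0.125 | km² | hexagonal cell area for aggregation |
| `quartile_cut` | Q3 | — | facility damaged iff its cell proportion **>** the cut quartile |
| `alpha` | 0.05 | — | two-sided level for all confidence intervals |

Both inequalities are deliberately strict; the boundary cases (fraction
exactly 0.40, distance exactly 25 m, cell proportion exactly at Q3) are
negative calls and are pinned by tests.

The 25 m rescue exists because geocoded facility points frequently fall
just outside their building's footprint. It is applied as a union with the
intersection rule: a facility inside an *undamaged* polygon but within 25 m
of a damaged polygon's centroid is still called damaged. This makes dense
urban fabric structurally false-positive-prone — a documented property of
the rule, not a bug. For the centroid dialect, where point-in-point
"intersection" is undefined, the facility takes the class of its nearest
centroid strictly within the same radius (separately configurable); exact
distance ties break to the lowest building id so that results are
order-independent. Facilities with no building object in range are reported
undamaged with basis `no_data`; the pipeline's default policy excludes
facilities lacking coverage from both models before evaluation (switchable
to retention).

## Hexagonal aggregation

Cells are flat-topped regular hexagons of exact area A, edge
`a = √(2A/(3√3))`, anchored at the lower-left corner of the data bounding
box. The centers form a triangular lattice whose Voronoi diagram *is* the
hexagonal tiling, so nearest-center search is an exact point-in-hexagon
test; ties within 1 nm resolve to the lowest cell id. Square cells are not
provided — hexagons have the lower quantization error and match standard
practice for fixed-area damage choropleths.

Quartile breaks are computed per model over the damaged proportions of
*non-empty* cells only (a quantile over undefined proportions is
meaningless), using linear interpolation between order statistics (numpy's
default; the estimator is an argument because the third quartile sits
directly in the decision rule). Each model is aggregated on its own
building set, since the two dialects identify different building
populations. When facilities from several cities are processed together,
quartiles should be computed per city by running the aggregation per city;
the library applies one grid per call and leaves the partitioning to the
caller or pipeline configuration.

## Evaluation statistics

Cohen's kappa is computed from the 2×2 joint distribution:
`κ = (p_o − p_e)/(1 − p_e)`. Its CI is the Wald interval with the
large-sample standard error `√(p_o(1−p_o)/(n(1−p_e)²))`, truncated to
[−1, 1]; a percentile bootstrap over resampled pairs is provided as an
alternative since no single CI convention dominates in practice. When both
raters are constant (`p_e = 1`) kappa is reported as flagged-undefined —
never silently 0 or 1. A useful degenerate case is pinned in the tests:
with marginals 0/13 and 1/13 the joint table is forced by the zero margin
and kappa is exactly 0.

Sensitivity and specificity intervals are exact Clopper–Pearson, computed
through beta quantiles (`Beta(k, n−k+1)` and `Beta(k+1, n−k)`); the test
suite checks them against an independent bisection of the binomial tail
equations to 1e-6 and verifies ≥ 93% empirical coverage at nominal 95%
(exact intervals are conservative). Zero-denominator estimates are returned
as flagged-undefined rather than raising, since single-class gold sets are
common in small strata.

Report tables give percentages to one decimal and sensitivity/specificity
point estimates to two decimals, always recomputed from the emitted counts.

## The synthetic-city generator

The generator emulates the documented structure of real post-earthquake
model output so that every downstream stage can be tested without external
data. It is first-class, seeded, and bit-for-bit reproducible from the
provenance block embedded in each city.

**Layout.** Rectangular footprints only: dense clusters of small buildings
(8–14 m sides, gaps drawn uniformly between 1 m and the 5 m merge
distance) and sparse singletons (minimum 15 m gaps), 30% of sparse
buildings large (25–60 m). Defaults: 400 buildings on a 2 × 2 km frame,
half in dense clusters — enough spatial structure for the aggregation
method at roughly the building-per-cell occupancy a mid-sized damaged city
produces, while keeping a full city cheap to regenerate.

**Damage field.** `fraction = clamp(exp(−d/d₀) + N(0, σ), 0, 1)` with
distance d from the footprint centroid to the epicenter, decay scale d₀ =
600 m and noise σ = 0.1 by default; buildings at fraction ≥ 0.8 are flagged
destroyed ("indistinguishable from rubble"). Exponential decay plus clamped
noise is the simplest field that concentrates damage spatially, which is
the property the aggregation method exploits; it does not attempt fault
geometry, soil effects, or building-vulnerability heterogeneity.

**Error modes** (defaults chosen to approximate the error frequencies seen
in satellite-imagery review of real model output — about a quarter of
dense-area polygon buildings affected by merging, about a fifth of large
buildings with multiple centroids, destroyed buildings missed at ~0.3, a
few percent of facility points geocoded just outside their building):

* *merging* (`p_merge = 0.25`): a horizontally adjacent dense-cluster pair
  is emitted as one rectangle spanning both footprints, with the
  footprint-area-weighted mean fraction — exactly the dilution mechanism
  that hides one damaged building inside a larger merged polygon;
* *multi-centroid* (`p_multi_centroid = 0.2`): a large building emits k ∈
  {2, 3} centroids (uniform), one per equal-width wing. Wing sub-fractions
  follow a concentrated-damage model: the damaged region is a contiguous
  span covering the building's fraction of its width from a seeded random
  end, so wing fractions average to the building fraction and a single
  damaged wing of an otherwise intact building yields a damaged centroid —
  the documented whole-building-flagged-by-one-wing error;
* *destroyed miss* (`p_destroyed_miss = 0.3`): a destroyed building is
  emitted with fraction uniform on [0, 0.2] (polygon dialect) or class 0
  (centroid dialect), i.e., clearly below any damage cut;
* *geocoding* (`geocode_sigma_m = 3`, `p_geocode_outside = 0.06`):
  isotropic jitter, or displacement to 1–5 m outside the host footprint
  into open ground (redrawn if the displaced point lands inside a
  neighboring footprint, so the error stays "just outside a building"
  rather than "inside the wrong building").

**Facilities.** Hospitals are hosted only by large buildings, pharmacies
preferentially (80%) by dense-zone buildings, dialysis centers anywhere;
one facility per building; the gold label is the thresholded true fraction
of the host. Host selection excludes undamaged buildings that have a
damaged building's centroid strictly inside the rescue radius: a facility
there would be flagged by the rescue rule however perfect the model output,
so its gold label would be structurally unrecoverable and "error-free
input ⇒ error-free calls" could not hold. This is a property of where
facilities are placed, not of the model-error simulation — injected errors
still degrade recovery in the usual way.

**What passing tests do and do not show.** The simulator demonstrates that
the pipeline's logic is correct and that its behavior responds to each
error mode in the expected direction. It does not certify real-world
accuracy: real footprints are not rectangles, real damage fields are not
radially symmetric, real geocoding error is heavy-tailed, and real model
errors are spatially correlated with imagery artifacts. Conclusions about
operational sensitivity/specificity require ground-truth validation.

## Numerical and degenerate-input choices

* Damage values with max > 1.5 on read are treated as percentages and
  divided by 100 (logged) — the 0–100 and 0–1 conventions are otherwise
  indistinguishable.
* Invalid polygons are repaired with shapely's validity-restoring
  decomposition; a self-intersecting bow-tie becomes its lobe union (area
  checked against hand-computed exact values in tests). Multipolygons split
  into parts, each keeping the parent's fraction with suffixed ids.
* Duplicate facilities: exact normalized-name match (lowercase, punctuation
  stripped, whitespace collapsed) AND projected distance < 10 m, closed
  transitively; each group keeps its first-encountered record. Idempotent;
  checked against a brute-force union-find oracle.
* Empty model inputs produce all-`no_data` call sets with a warning, never
  a crash; fewer than 4 non-empty cells make quartiles an error.
* Benchmark seeds are derived through `numpy` `SeedSequence` from the
  user-facing seed, keeping every derived seed below 2³¹.

## Problem sizes used in tests and the acceptance script

Simulation-backed checks run on 150-building cities on a 1.2 km frame with
46 facilities (4 hospitals, 2 dialysis, 40 pharmacies) and a 350 m decay
scale — small enough that brute-force O(n²) oracles are exact companions,
large enough that every error mode fires. Monte-Carlo sweeps use 100 seeds
per error level; interval coverage uses 2,000 binomial draws per (p, n)
condition. These sizes are the package's test conditions, chosen once;
the library itself has no such limits.

## Known limitations

* The rescue radius, damage cut and quartile rule are operating points, not
  validated optima; sensitivity analyses over these thresholds are the
  caller's responsibility (all are plain arguments).
* Aggregated calls estimate "facility in a heavily damaged area", not
  damage to the facility itself.
* The local projection is per-city; continental-scale inputs should be
  partitioned before processing (the reader warns beyond ~3° from the
  projection origin).
* Kappa's Wald interval is anti-conservative near |κ| → 1 and small n; use
  the bootstrap alternative there.
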