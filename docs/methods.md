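# Methods

This note documents the models and procedures implemented in `priorigrid`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic data can and cannot show.

## Analysis grid

The study area is tiled with square cells in WGS84 decimal degrees; no map
projection is applied anywhere. `make_grid` snaps the requested extent
outward to whole multiples of the resolution (default 0.5°), so the grid
tiles the expanded extent exactly. Cells are indexed row-major from the
south-west corner; cell intervals are half-open `[min, max)`, closed on the
grid's outermost north/east edge so that every point of the extent maps to
exactly one cell. Nominal areas use a flat 110 km/degree convention — a
0.5° cell covers 55 km × 55 km = 3025 km² — deliberately ignoring the
latitudinal convergence of meridians; curvature-corrected areas are out of
scope. Cells straddling any real-world boundary are treated uniformly
(no clipping to administrative polygons).

## Occurrence handling

Occurrence CSVs are DarwinCore-like (`species_id`, `decimal_longitude`,
`decimal_latitude`; extra columns ignored). Cleaning is deliberately
minimal and fully accounted: records with missing or non-numeric
coordinates, records for species absent from the catalog, and records
outside the grid extent are dropped, each with its own counter, and
`records_read = retained + Σ dropped` always holds. "Detailed locality
information" is operationalized as parseable coordinates. Subspecific taxa
are treated as distinct `species_id` values; no name resolution is
performed. The incidence matrix is boolean species × cell occupancy, so it
is idempotent under duplicated records and invariant to record order.

## Hotspot identification

**Composite richness.** For each of the five groups (ALL, ENDEMIC,
THREATENED, CITES, NATIONAL_PROTECTED) the per-cell ratio `r_gc = S_gc/N_g`
is computed over occupied cells and summed into `R_c ∈ [0, 5]`. An empty
group contributes zero with a warning rather than failing, since small
study systems may lack, say, CITES species.

**Top-fraction selection.** `K = round(fraction × n_occupied)` with
`fraction = 0.05` by default; an explicit `k_override` reproduces analyses
that fix K directly. All cells tying the K-th score are retained
("tie extension"), which is why selections of slightly more than K cells
can occur.

**Greedy complementarity.** The selection criterion is the count of
still-uncovered species (the most literal reading of "highest number of
remaining species"); an alternative criterion that maximizes the composite
gain directly is available as `criterion="composite_gain"`. Ties break by
larger composite gain, then smaller cell id. Gains are sums of rationals
`a/N_g`; a 1e-9 tolerance absorbs float summation-order noise in tie
comparisons (distinct gain values differ by at least 1/lcm of the group
sizes, far above the tolerance at realistic N_g). A species with zero
occurrences makes the cover infeasible and is rejected up front.

**Integration.** "Order" means the 1-based rank position within each
algorithm's hotspot list, not the raw score — the two scores live on
different scales. First-class cells (in both lists) sort by the sum of
their two orders; second-class cells (in exactly one list) sort by their
single order; ties break by larger (summed) score, then smaller cell id.
The two classes are kept separate rather than interleaved. When the
intersection alone exceeds `k_total`, it is truncated by order sum.

## Pattern correlations

Ten pattern vectors (5 groups × 2 algorithms) are formed over *all* grid
cells with absent cells zero-filled: group ratios for the richness side,
the group components of the complementarity gains (nonzero only on
selected cells) for the other. Pearson's r is computed with a two-sided
t-test p-value; a `none|zscore|minmax` normalization switch exists for
procedural fidelity, but r is affine-invariant so the choice cannot change
results (this is property-tested, not assumed). Correlation strength uses
the seven-class |r| taxonomy (perfect / very strong / strong / moderate /
weak / very weak / none); r is rounded to two decimals before
classification, because reported correlations carry two decimals and the
class must match the printed value. Group ratios, not raw counts, are
correlated by default (switchable); no multiple-testing correction is
applied. The pipeline drops constant (all-zero) patterns — e.g. an empty
group — from the correlogram with a notice, as their correlation is
undefined.

## Reserve overlay and gaps

Reserves are (multi)polygons with a `national` or `provincial` tier; other
tiers are rejected by design (lower-tier reserves are outside the
analysis's scope). Invalid rings are repaired with `shapely.make_valid`. A
cell counts as covered when its box has positive-area intersection with
any reserve of the chosen tiers — touching along an edge does not count; a
centroid-in-reserve rule is available for sensitivity runs. No minimum
overlap fraction is imposed, since none is defined for the source
analysis. Gap analysis partitions hotspot cells into covered and gap sets;
the coverage report tallies, for every area class (all occupied cells,
hotspots, hotspots covered by each tier and their union, the corresponding
gaps, and whole-network coverage), the species present in at least one
member cell per group, with proportions of `N_g`, formatted
"count/percent" with percentages rounded to the printed precision. The
three-way composition partition (threatened / endemic-excluding-threatened
/ remaining) is exact and disjoint by construction.

## Suitability post-processing

The distribution model itself (e.g. a maximum-entropy model) is external;
the pipeline consumes its continuous per-species output rasters in ESRI
ASCII format, values in [0, 1], at a fine resolution that divides the
coarse grid (default 5 arc-min, i.e. 6 × 6 sub-cells per 0.5° cell).

- **Modeling filter:** only group members (default THREATENED) with at
  least `n_min = 5` records are modeled.
- **Replication plan:** 5–29 records → jackknife with one replicate per
  record; 30 or more → 10-replicate cross-validation. The breakpoint
  assigns exactly 30 to the cross-validation branch (the source rule
  leaves 30 unassigned between "5–29" and "more than 30"); it is
  configurable.
- **Predictor screen:** while any pair of candidate variables has
  |r| > 0.70 (strictly), the member of the worst pair with the larger mean
  absolute correlation to the remaining variables is removed. The removal
  choice is a heuristic the source does not specify; this one is
  deterministic and guarantees max pairwise |r| ≤ 0.70 on output. A 1e-12
  tolerance keeps pairs at exactly the cutoff from being removed through
  round-off. Constant variables are rejected (undefined r). A separate PCA
  step is not implemented; screening is by the correlation rule alone.
- **Threshold and superposition:** per pixel, species with suitability
  `v ≥ τ` (τ = 0.75, inclusive — values *less than* 0.75 are rejected)
  contribute `v` to the community map `V_x`; the SHA mask is `V_x > 0`.
  Raw sums are exported without rescaling.
- **Coverage classes:** a coarse cell is *complete* when all its fine
  sub-cells are SHA-positive, *partial* when at least one is, *none*
  otherwise; a fractional-coverage threshold can replace the all-sub-cells
  rule. "Completely covered" had no formal definition in the source; the
  sub-cell decomposition is this package's operationalization.
- **Stability:** long-term stable SHA is the pixelwise intersection of the
  scenario masks; a coarse cell is "in stable habitat" when complete under
  the stable mask, and stability is cross-tabulated against gap and
  reserve cell sets.

## Synthetic study system

The generator emulates a herbarium-scale prioritization study so every
stage runs end to end with planted, recoverable structure. A single
integer seed drives independent sub-streams for the catalog, occurrences,
reserves, and suitability stages, so regenerating one product never
perturbs the others; all outputs are bit-reproducible under a fixed seed.

- **Catalog** (default 2000 species): group memberships drawn
  independently per species at the study rates — endemic 32.9%, threatened
  6.4% (VU/EN/CR uniform), CITES 3.5%, nationally protected 0.8%.
  Memberships overlap freely, as in the real catalog.
- **Occurrences:** each species receives a uniform range center and a
  log-uniform record count on [3, 2500]; records scatter isotropically
  (sd = 1°) around the center and wrap at the extent boundary (toroidal
  edges). The record-count bounds were calibrated once, by simulation,
  so the generated range-size quantiles match the study's reported ones
  (≈9% of species occupying < 5 cells, ≈66% occupying > 20 cells); with
  no boost the expected record density is exactly uniform, which the
  wrapped edges make testable. Toroidal wrapping trades realism at the
  extent boundary for freedom from edge artifacts — appropriate for a
  test-bed, not a landscape model.
- **Planted hotspots** (default 10 cells, kept ≥ 3 cells apart as distinct
  "mountain systems"): planted cells carry a relative record-sampling
  weight `hotspot_boost` (default 10, ordinary area 1) — each record's
  location density is the species' Gaussian multiplied by the cell weight.
  This emulates the collection bias of heavily surveyed localities: every
  species whose range touches a planted cell concentrates records there,
  so planted cells accumulate species of all five groups and sit far above
  the non-planted composite-richness distribution (the planted minimum
  typically exceeds the background 95th percentile by a wide margin),
  while their neighbors are not inflated. With `hotspot_boost = 1` the
  mechanism vanishes and density is uniform.
- **Reserves:** random rectangles, alternating national/provincial, are
  accepted (and shrunk at the margin by bisection) until the union covers
  the requested fraction of the extent to within ~1%.
- **Suitability:** per species, an isotropic Gaussian suitability bump
  (peak in [0.8, 1.0], sd in [0.8, 1.5]°) around a niche center; the
  future scenario shifts the center north by `future_shift_north`
  (default 2°). Niche centers are drawn from an inset margin of the extent
  so neither the current nor the shifted bump is truncated at the
  boundary, keeping the planted shift cleanly measurable from the rasters.

**What passing tests show — and do not.** The synthetic system plants
structure (high-diversity cells, coverage fractions, a known shift) and
the tests verify the pipeline recovers it. Real specimen data differ in
ways the generator does not emulate: spatially autocorrelated and
road-biased collection effort, taxonomic error, non-Gaussian and
climate-driven range shapes, boundary effects of a real coastline, and
group memberships that are ecologically correlated rather than
independent. Recovery of planted hotspots therefore demonstrates
correctness of the algorithms, not robustness of hotspot inference to
survey bias.

## Problem sizes and numerical choices

Default test and demonstration runs use a 10° × 10° extent (400 cells of
0.5°), 2000 species, ≈0.75 M records, and 40–60 modeled species at 5
arc-min — sizes chosen so a full pipeline run takes seconds while keeping
every group non-degenerate (the smallest group, nationally protected
species, still has ~16 members at 2000 species). Tie-breaking is
deterministic everywhere (score, then smaller cell id). Percentages are
rounded only at the formatting layer, never inside computations.

## Known limitations

- Nominal areas ignore meridian convergence; range areas in km² are
  conventions, not geodesy.
- The greedy cover is a heuristic; optimal set cover and spatial
  contiguity constraints are out of scope.
- The coverage rule ("any positive-area overlap") can count a cell as
  protected on a sliver intersection; use the centroid rule to probe
  sensitivity.
- Suitability post-processing assumes all rasters share one geotransform
  aligned with the coarse grid; resampling is not provided.
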