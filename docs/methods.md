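# Methods

## The index model

AHAH summarises 14 neighbourhood measures in three domains — retail
environment (5 network distances to hazards), health services (5 network
distances to services), physical environment (green-space buffer area and
3 pollutant concentrations) — into one score per small statistical zone.

The construction is entirely rank-based after aggregation, which makes it
invariant under any strictly monotone transformation of a raw indicator
(changing km to miles, or µg/m³ to ppm, changes nothing downstream; this is
asserted by test). The steps, with conventions as implemented:

1. **Orientation.** Each indicator is signed so that larger = less
   healthy. Distances to hazards and green-space area are negated
   (proximity to a bookmaker is unhealthy; abundant green space is
   healthy); distances to services and pollutant concentrations are kept.
2. **Rankit.** Each oriented indicator is transformed to standard-normal
   scores `Φ⁻¹((r − ½)/N)` with ascending ranks `r` (average ranks for
   ties). The plotting position `(r − ½)/N` is the Rankit definition;
   alternatives (Blom `(r − 3/8)/(N + ¼)`, van der Waerden `r/(N+1)`) were
   deliberately not offered, to keep a single canonical standardisation.
   `Φ⁻¹` is `scipy.special.ndtri`, accurate to well below the package's
   own 1e−10 contract over `(1e−8, 1−1e−8)` (verified against a 30-digit
   `erfinv` oracle in the tests).
3. **Domains.** Equal-weight means of the member Rankit scores (5, 5 and 4
   indicators; leisure centres belong to the health-services domain). The
   weight vectors are explicit configuration (`0.2…`, `0.25…`, domain
   weights `⅓…`) so users can re-weight; weighted sums divide by the
   weight sum *after* the dot product so the equal-weight default is an
   exact mean.
4. **Exponential rank transform.** Each domain score is ranked
   (ascending, rank 1 = most health-promoting), scaled to
   `R = rank/N ∈ (0, 1]`, and mapped through
   `X = −23·ln(1 − R·(1 − e^(−100/23)))`. Analytically `X(1) = 100`
   (`ln(e^(−100/23)) = −100/23`) and `X → 0` as `R → 0`; the curve is
   convex, so worst-ranked zones are emphasised and a single bad domain
   cannot be averaged away by two good ones ("cancellation resistance",
   asserted as an inequality against linear rank-averaging).
5. **Index.** Equal-weight mean of the three domain `X` values, then
   ordinal ranks and deciles. **Polarity:** scores increase with
   unhealthiness; rank 1 and decile 1 are the most health-promoting. The
   deposited real-world dataset does not fix a numeric polarity, so this
   package states its convention in every output header description and
   keeps it consistent across components, domains and index.

**Ties.** Inside Rankit, ties take average ranks (a statistical
convention). For `R`, deciles and reported ranks, ties are broken
*ordinally by zone code* so that every `R` is distinct, `X` is well
defined, and deciles partition into groups of ⌊N/10⌋ or ⌈N/10⌉ zones
exactly. A real deposited dataset may resolve ties differently; with
continuous indicators ties are measure-zero.

**Degenerate inputs.** A single zone gets Rankit score 0, `R = 1`,
`X = 100` in every domain and index 100. Zero-variance indicators are
legal (all ranks tied); zero-variance columns in the correlation
diagnostics are reported with an explicit `undefined` marker rather than
propagating NaN.

## Accessibility (routing) stage

The road network is a directed weighted graph; one-way edges are stored in
one direction only. Points snap to the nearest *node* by Euclidean
distance (ties to the smallest node id); snap legs are excluded from the
reported distance but the snapped nodes are reported for audit. Shortest
paths minimise distance (km), not travel time.

Distances are carried internally as integer micro-kilometres (edge lengths
are 6-decimal km by contract, so the scaling is lossless). Integer
summation makes path lengths independent of summation order, so the
production algorithm — one Dijkstra per distinct snapped facility node on
the edge-reversed graph, then a per-origin minimum with smallest-node-id
tie-break — is *exactly* equal to the brute-force forward per-pair
minimum, which the tests assert with zero tolerance on 20+ random
strongly connected graphs. An origin with no reachable facility is an
error listing the postcodes, or `inf` under `allow_unreachable`.

## Physical-environment stage

**Green space.** The area measure is the *clipped* intersection between a
postcode's circular buffer (default 900 m, the ~15-minute-walk radius;
600/700/800 m supported for sensitivity) and the union of green polygons —
overlaps are not double-counted and the result is bounded by the buffer
area. The alternative reading (total area of every polygon touching the
buffer) is available as `green_area_mode: whole_polygon`. Buffers are
regular polygons with a fixed 64 segments per quarter circle, so results
are deterministic across platforms and slightly below πr² (relative error
~1e−4 at 64 segments). Buffers are Euclidean, not network-based, matching
the buffer-zone definition of the measure.

**Zonal pollutant means.** The unweighted mean of all 1×1 km cells whose
square footprint intersects the zone with positive area (`footprint`
rule); a `centre` rule (cell centre inside zone) is available. Nodata
cells are excluded; a zone whose overlapping cells are all nodata is an
error, not a silent NaN. The test oracle rasterises the zone at 10 m and
collects the parent cells of intersected fine cells; any positive-area
overlap contains an interior point and hence an intersecting 10 m subcell,
so oracle and implementation coincide for the randomly shaped test zones.

## Aggregation

Postcode measures (distances and green area) aggregate to zones by the
unweighted arithmetic mean; zone population is metadata only. The same
rule is used for green space for consistency, since distance indicators
define the aggregation convention.

## The synthetic study region

The generator emulates the *statistical and spatial structure* of the real
inputs, not their content:

- **Geometry.** Planar Cartesian metres in a square extent (default
  20 km); no geographic CRS or reprojection anywhere. Zones are a grid
  partition (default 50 zones) with populations drawn uniformly in
  [500, 3000] (spanning LSOA/DZ sizes); postcodes (5–20 per zone) are
  uniform within their zone.
- **Road network.** A perturbed lattice (~1.25 km spacing, node jitter
  ±20%); edge lengths are the Euclidean distance inflated by up to 25% and
  rounded *up* to 6 decimals, so network distance always dominates the
  straight line. 10% of edges are made one-way, each conversion accepted
  only if strong connectivity survives (then verified globally).
- **Urban structure.** Service points of all 10 categories cluster around
  the extent centre (half-normal radius with scale
  `urban_fraction · extent/2`, default 3 km, plus a 10% uniform
  background); pollutant surfaces are a Gaussian bump over the same core
  plus seeded noise (NO₂ 6+34, PM₁₀ 9+14, SO₂ 0.5+4 amplitude, in
  concentration units); green polygons (default 120 rectangles,
  100–600 m sides) are accepted with probability `(d/dmax)^1.5`, denser
  towards the periphery. Facility counts per category (30 fast food … 3
  hospitals) follow the relative prevalences of such services in a
  mid-sized region.
- **Bands.** Zones are labelled core / suburban / remote by the rank of
  their centroid distance from the centre, with cut-offs at the 0.35 and
  0.75 quantiles. The cut-offs are a design choice anchored in the model:
  with all services and hazards clustered at the core, a zone at distance
  quantile `q` has domain rank fractions ≈ `(1−q, q, 1−q)` and idealised
  index `[2·X(1−q) + X(q)]/3`, which is minimised at `q ≈ 0.67`; the
  suburban band brackets that minimum, which is what makes the
  "suburbs healthiest, cores and remote areas worse" pattern a structural
  property of the generated world rather than a fluke of one seed
  (asserted on three seeds).
- **Determinism.** One global seed fans out to fixed per-component child
  streams (`SeedSequence(seed, spawn_key=(k,))` for network, zones,
  postcodes, services, green, rasters), so adding a component never
  reshuffles the others. All coordinates are generated pre-rounded
  (0.1 m; zone corners 0.01 m; raster values 0.001) and all writers use
  fixed-width decimal formats, so write→read round-trips are exact and
  two runs with one seed are byte-identical.

**What the generator does not emulate** — and therefore what passing tests
do *not* establish about real data: real road topology (no dual
carriageways, no disconnected islands, no speed limits or barriers beyond
edge absence), population-weighted postcode centroids (points are
uniform), realistic pollutant chemistry or dispersion, green-space shape
complexity, and any correlation between zone population and density. The
pipeline's *correctness* (routing, geometry, transforms) is established by
oracles independent of the generator; the *structure-recovery* result is a
statement about the generator's idealised urban model only.

## Problem sizes and numerical choices

Default study conditions: 50 zones, ~250–1000 postcodes, 256 network
nodes, 10 categories (≈6,800 origin-category routings), 20×20 km rasters.
The test-suite oracles use 20 random graphs of 60–200 nodes for routing,
10⁶ Monte-Carlo samples for the buffer-area check (standard error well
inside the 1% band), and 10 random convex zones for the zonal-mean check.
Tolerances: routing and zonal means exact (integer arithmetic / identical
cell sets); Rankit 1e−10 against the high-precision oracle; `X(1) = 100`
to 1e−9; Monte-Carlo 1%.

## Known limitations

- Snap legs are excluded from distances; with a ~1.25 km lattice the snap
  gap can be a noticeable fraction of short distances. The real-world
  routing engine's handling of this step is unspecified, so the simplest
  reproducible contract was chosen and the snap distance is reported.
- The exponential transform is applied to domain ranks only; the combined
  index is the mean of the three `X` values, re-ranked solely for deciles.
- Aggregation is unweighted; population weighting is intentionally out of
  scope.
- The correlation diagnostics are descriptive; no causal weighting of
  indicators is attempted.
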