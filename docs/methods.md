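# Methods

This note documents the models, conventions and design decisions behind
`edgegrid`, in the order the pipeline applies them.

## Coordinate system and grids

All areal quantities are computed in a spherical Lambert azimuthal
equal-area (LAEA) projection on the WGS84 authalic sphere
(R = 6 371 007.181 m), centred by default on the occurrence centroid (or on
a fixed scenario centre for synthetic runs). On the sphere the projection
is exactly equal-area; against the WGS84 ellipsoid the local areal error at
mid latitudes is well under 0.5 % (tested on a 1° geodesic square), which
is negligible relative to the IUCN threshold spacing (factors of 4–50
between category boundaries).

Grid cells are half-open squares `[x0 + i·s, x0 + (i+1)·s)` so every point
belongs to exactly one cell. Three sizes are used: 2 km (AOO, the IUCN
standard), 10 km (locations) and 5 km (mapping/hotspots). The grid origin
defaults to the projection origin and is configuration; AOO and location
counts depend on it through cell-boundary effects, which is inherent to
grid-based occupancy measures. The origin is serialized into every run
(`projection.json`) so results are recomputable.

Exact duplicate lon/lat records collapse to one point before any geometry
(EOO/AOO are defined on occupied space, not record counts); near-duplicates
are kept.

## Criterion B

EOO is the convex-hull area of the projected points (shapely). Fewer than
three non-collinear points give EOO = 0 with a degeneracy flag; rather than
a special category, the *EOO-floor* rule `effective EOO = max(EOO, AOO)`,
applied at assessment time, handles these (it is also the IUCN convention
that EOO may not be smaller than AOO). AOO is (occupied 2-km cells) × 4 km²;
locations are occupied 10-km cells — a deterministic, origin-documented
approximation of the IUCN "location" concept rather than threat-specific
circles.

Thresholds live in one editable table (`CriterionBThresholds`), never in
logic: B1 on effective EOO (100 / 5 000 / 20 000 km²), B2 on AOO
(10 / 500 / 2 000 km²), both gated by location counts (1 / ≤5 / ≤10); the
category is the more severe of the two subcriterion ranks. Condition (b)
of Criterion B (continuing decline) is assumed satisfied, as in automated
occurrence-based assessments; outputs are therefore *preliminary*
categorizations.

**NT buffer.** The threshold tables define CR/EN/VU only; distinguishing NT
from LC requires a convention. The buffer assigns NT when the VU
thresholds are missed by ≤ 50 % (effective EOO < 30 000 km² or
AOO < 3 000 km², with ≤ 15 locations). It is enabled by default — the
pipeline's category spectrum and the GE weighting both distinguish NT from
LC, so a buffer must be active to ever produce NT — and can be disabled
(`nt_buffer=False`), collapsing NT into LC.

## Criterion A

The unit of analysis is the occupied 2-km AOO cell (matching "potential
decrease in AOO" as the population-reduction proxy); an occurrence-level
mode exists for sensitivity analysis. A cell is threatened iff the majority
land-cover class among its pixels (raster layers) or the class at its
centroid (polygon layers) is in the configured threat set. Pixel-count ties
resolve to the smaller class code, which is deterministic; with the default
codes this errs toward "threatened". The default threat set emulates the
CORINE convention: artificial (1xx) and agricultural (2xx) classes minus
olive groves (223) and the agriculture/natural mosaic classes (243, 244).

Reduction = 100 × threatened / known cells; cells with no land-cover data
are excluded from the denominator and counted. All-unknown taxa are DD
under Criterion A. Category thresholds are the IUCN A2 values
(CR ≥ 80 %, EN ≥ 50 %, VU ≥ 30 %) plus a configurable NT buffer at 20 %.
No temporal window (10 years / 3 generations) is modelled: the proxy is a
static habitat-quality snapshot.

## Combination and validation

Combination is the join on the severity lattice CR > EN > VU > NT > LC
(commutative, associative, idempotent); DD is the identity element, so a
taxon DD under one criterion takes the other criterion's category, and DD
under both stays DD. Validation aggregates to threatened (CR ∪ EN ∪ VU) vs
not (LC ∪ NT), with threatened as the positive class; DD rows on either
side are excluded, mirroring reference sets that drop data-deficient taxa.
Accuracy and sensitivity are the primary scores; specificity and balanced
accuracy are emitted as clearly labelled extras. Sensitivity is NA when the
reference contains no threatened taxa.

## ED and EDGE

Fair-proportion ED divides each branch equally among the tips below it;
the implementation is a two-pass traversal (post-order descendant counts,
pre-order accumulation), O(n). Its defining invariant — Σ ED over tips
equals the total branch length (phylogenetic diversity) — is tested to
1e-9 relative on random trees against a brute-force path-walk oracle.
Polytomies are used as given; no resolution is imposed. EDGE uses natural
logarithms throughout: `EDGE = ln(1 + ED) + GE·ln 2` with GE = 0…4 from LC
to CR, so one category step adds exactly ln 2 (a two-fold risk increase).
GE is taken from the **combined** A/B category. Taxa absent from the tree,
or DD, receive no score and are excluded from spatial EDGE means (counted
in the run report).

## Surfaces, hotspots, gap analysis

Taxa are rasterized to 5-km presence cells; per-cell statistics are
endemic richness, threatened richness, CR richness and the arithmetic mean
EDGE over scored taxa present (NA where none occur). L1 hotspots for a
metric are the cells at or above the k-th largest value, k = ceil(q·n)
with q = 0.01 over *eligible* cells — cells holding ≥ 1 endemic taxon.
Restricting the quantile to occupied cells (the default; an all-cells mode
exists via the surface itself) avoids the degenerate outcome where empty
sea/background cells make every occupied cell "top 1 %". Ties at the
threshold are included, so hotspot sets can exceed 1 % — markedly so for
small-integer metrics like CR richness, where many cells share the
threshold value; this is a property of quantile selection on discrete
metrics, not an artefact.

PA overlap intersects the full square cell polygon with the PA set
(shapely STRtree); a centroid-membership mode is available. Percent inside
and outside always sum to exactly 100.

## Synthetic scenarios

The generator emulates the study setting: a Greece-sized 500 × 400 km
domain, a projection centre at (22° E, 38.5° N), protected areas covering
28 % of the domain (the Natura 2000 coverage figure used as the default),
a 100-Myr ultrametric tree, and a land-cover mosaic with a configurable
threat fraction (default 0.30) plus a 5 % excluded class (code 223) to
exercise the olive-grove exclusion.

Per-taxon ranges are designed to land in a target Criterion B category *by
construction*: cluster centres are snapped to centres of distinct 10-km
location cells (cluster points are truncated at 2.5 km, inside the cell),
so the location count is exact, and the box the cells are drawn from
bounds EOO below the relevant threshold. The designs are CR: 1 location;
EN: 2 locations within a 60-km box (hull < 3 600 km² < 5 000); VU: 7
locations (blocks EN's ≤ 5-location gate while B2-VU triggers on the small
AOO); NT: 12 locations (blocks VU's ≤ 10 gate, NT buffer applies); LC: 18
locations (> 15 blocks the buffer). The default mix is 30 % CR, 20 % EN,
20 % VU, 15 % NT, 15 % LC over 200 taxa. Criterion A ground truth is
induced, not designed: ranges land on land cover of known threat fraction.

Land-cover threat pixels are assigned by exact count then shuffled, so the
realized fraction matches the target to within one pixel. PA rectangles
are whole blocks of a 25-km partition plus one shrunken block, hitting the
target coverage exactly and guaranteeing non-overlap. The tree is a Yule
process (exponential waiting times at rate proportional to lineage count)
rescaled to the root age. One integer seed drives all four generators
through `numpy.random.SeedSequence` spawning, giving byte-identical reruns.

**What the generator does not emulate:** realistic range-size frequency
distributions, spatial autocorrelation between land cover and occurrences,
beta diversity, taxonomic structure, or observation/collection bias.
Passing tests therefore demonstrate the *correctness of the computations*
under designed conditions, not the field accuracy of preliminary
assessments on real floras.

## Numerical choices and problem sizes

- Severity ties in combination are trivial (the join of equals).
- Hotspot thresholds are computed by descending sort, not interpolated
  percentiles, so the ceil(q·n) membership bound holds exactly.
- Default test/acceptance problem sizes: 200 taxa (~6 000 occurrence
  records), a 500 × 400 raster at 1-km pixels, trees to 128 tips, 100
  random replicates per geometry oracle; the full pipeline runs in seconds
  and is deterministic per seed.
- The validation accuracy on the default scenario is below 1 because
  Criterion A responds to the (random) land cover, not to the Criterion B
  design — taxa designed NT/LC whose cells happen to exceed the 30 %
  threat majority become VU, a deliberate feature of the combined design.

## Known limitations

- Locations are grid cells, not threat-delimited areas; counts are
  origin-dependent like all gridded occupancy measures.
- No severe-fragmentation test, subpopulation clustering, or
  continuing-decline estimation (Criterion B conditions beyond range size);
  no Criteria C/D (population data are out of scope).
- No land-cover change detection between epochs; Criterion A is a
  habitat-quality snapshot.
- The PA gap analysis is purely geometric (intersection), with no
  management-effectiveness weighting and no terrestrial/marine clipping.
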