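# Methods

This note records the models implemented in `greenblue`, the assumptions
behind them, the defaults and why they hold, and what the synthetic
fixtures do and do not demonstrate.

## Raster model

A `RasterGrid` is a 2-D array with cell (0, 0) at the top-left and the
`origin` at the world lower-left corner — the usual raster convention, used
consistently by all modules. A single nodata sentinel per grid is
propagated, never interpolated. Preprocessing operators follow the standard
GIS semantics: mosaic is first-tile-wins on overlap; masking keeps a cell
iff its centre lies in the boundary polygon; resampling aggregates whole
blocks (block mean for continuous grids, block-representative cell for
categorical ones) and truncates partial blocks at the bottom/right edge.
GeoTIFF I/O stores georeferencing in the `ModelPixelScale` /
`ModelTiepoint` tags plus the GDAL nodata tag; the ESRI ASCII grid
reader reports malformed headers with the offending line number.

## Minimum cumulative resistance (MCR)

The resistance surface is a strictly positive reclassification of land-use
categories. Cost accumulates per step as
`step length × (R_current + R_next)/2`, step length = cell size
(orthogonal) or cell size × √2 (diagonal) — the accounting of the standard
cost-distance tools, chosen because the formulation `Σ D_ij R_i` is
ambiguous between per-cell and per-edge accounting. The monotone response
function of the MCR formulation is taken as the identity: any strictly
increasing choice preserves path ranking, so corridor geometry, `L_ab`
ratios and everything downstream are invariant to it.

Cost distance is an in-repo Dijkstra on the implicit 8-connected grid
graph (flat arrays, lazy-deletion heap). Ties in cost resolve toward the
geometrically shorter path, then lower cell index, so outputs are
deterministic. All cells of a patch act as zero-cost sources — the
automated replacement for manually placed source points; a centroid-source
run can be emulated by passing a single-cell source set. Corridors are
single-cell-wide least-cost chains; widths/buffers are presentation only.

## Hydrology (blue corridors)

Depression filling is priority-flood with an ε step of `1e-6 × cell size`,
so every filled flat drains strictly toward its spill point. D8 directions
use drop/distance with a fixed clockwise-from-east tie-break
(E, SE, S, SW, W, NW, N, NE); nodata and off-grid neighbours act as
outlets. Accumulation counts upstream cells excluding the cell itself (the
dominant GIS convention) and is computed by a topological pass that
detects cycles (the signature of an unfilled input). Streams are traced
where accumulation ≥ threshold (default 1% of the cell count), broken into
segments at confluences, Strahler-ordered, and classified by peak
accumulation: mainstream (≥ the mainstream bar, default 5% of cells),
tributary (≥ the stream bar), runoff (traced from the lower runoff bar,
default 0.5%, replacing any manual tributary picking with a configurable
rule).

## Connectivity (PC / dPC)

The dispersal kernel is the negative exponential through the calibration
pair (2 000 m, probability 0.5): `p(d) = 0.5^(d/2000)`. The reference
distance is read as the half-decay distance, not a hard cutoff, because it
is stated together with its probability; no distance truncation is applied.
Inter-patch distance is the minimum edge-to-edge distance between boundary
cell centres. `p_ij` maximizes the product of step probabilities over patch
sequences, computed as a minimal-sum path on −log p. `PC = (a'Pa)/A²` over
all ordered pairs including i = j. `dPC` removes a patch's matrix rows,
columns and area while **keeping A fixed** (the removal formula prescribes
no re-normalization) and is computed incrementally from the pair sum; the
given `p_ij` matrix is not re-routed around the removed patch. Scores are
normalized so the maximum is exactly 100 (computed as `(x/max)·100`, which
is exact in IEEE arithmetic); GPA selection keeps normalized dPC strictly
above 10.

## Gravity model

`G_ab = L_max² ln(S_a S_b) / (L_ab² P_a P_b)`. The patch resistance `P` is
the mean of the resistance surface over the patch's cells (the quantity is
never defined elsewhere; a dominant-class variant can be had by
reclassifying first). Areas enter in **hectares** by default: the formula
needs `S_a·S_b > 1` for a positive logarithm, and sub-km² patches — the
synthetic fixtures' scale — violate that in km². The unit is configurable
(`area_unit`: m2/ha/km2); it affects `G_ab` only through a monotone
rescaling, but the "normalized > 2" cutoff is unit-sensitive, which is why
the default is documented here. Candidate corridors need normalized
`G_ab > 2` (strict) and both endpoints among the selected GPAs.

## Network selection and indices

Candidate links are deduplicated per patch pair (keeping the higher
`G_ab`). The five pruning principles run as deterministic passes:

1. *Parallel bundles*: links whose mean symmetric chain distance is below
   `parallel_dist_cells` (default 5) are grouped (union-find); each group
   keeps its best-ranked member.
2. *Detours*: a direct corridor A is dropped when legs B + C through an
   intermediate GPA are both present and `|L_A − (L_B + L_C)|/L_A ≤ ε`
   (default 0.15).
3. *Ranking*: retention rank is `G_ab · (1 + w · blue_fraction)` where
   `blue_fraction` is the share of chain cells within `blue_buffer_cells`
   (default 2) of a stream cell and `w` is the blue weight (default 0.5).
4. *No isolates*: an isolated GPA gets its best-ranked candidate link back.
   Because "every GPA connected to the others" is read here as one usable
   network, remaining components are then bridged greedily with the
   best-ranked cross-component candidate links; if the candidate graph
   itself is disconnected a warning reports the components.
5. Principle 5 (blue preference) acts through the rank in step 3.

Scenarios come from a documented grid over (parallel distance, detour
tolerance, blue weight); duplicates by link set are discarded. Indices:
`α = (l−v+1)/(2v−5)`, `β = l/v`, `γ = l/(3(v−2))`, `CR = 1 − l/d` with
`d = Σ L_ab` over the network's links. `γ`'s denominator is the planar
maximum, so dense small candidate graphs can exceed 1. The final scenario
maximizes (γ, β, α) with minimal CR as tie-break — the comparison
procedure names no selection criterion, so this composite is an explicit,
overridable stand-in; the full metric table is always reported.

## Ecological nodes

By default the analysed surface is the multi-source cumulative-cost (MCR)
surface from all selected GPAs — its iso-lines are the "equivalent
resistance lines centred on the GPAs", and its saddles are the corridors'
constrictions; a raw-resistance mode is available (`node_surface`).
Ridge lines are stream extraction on the negated surface. Their default
threshold is 0.2% of the cell count, deliberately below the stream
default: a saddle is the watershed divide of its own crest line, so crest
accumulation is smallest exactly at the points of interest and a high bar
truncates the ridge there. Raw intersections are corridor cells within one
cell (Chebyshev) of a ridge cell — one cell absorbs the discretization
mismatch of two one-cell-wide rasterized lines. Intersections within the
merge radius (default 10 cells) collapse, union-find style, into one node
placed at the member cell nearest the cluster centroid, so every node lies
exactly on a corridor.

## Synthetic landscapes and what they show

The generator builds: a tilted base plane; Gaussian-profile ridges;
incised valleys along polylines; a **cross-valley slope** term (elevation
growing with distance to the nearest valley centreline, default 3 m per
30 m cell ≈ 10% grade, typical of dissected mountain terrain) that makes
the planted valleys the landscape's actual drainage system; and seeded
uniform noise smoothed by one 3×3 mean pass (the smoothing prevents
single-cell pits from dominating the fill). Land-use categories follow
elevation bands on the min–max normalized DEM with seeded per-cell jitter
(default 5%), water forced on valley centrelines. GPA patches are discs
placed on the forest band by seeded best-candidate (blue-noise) sampling —
each new centre is the farthest-from-existing among a pool of valid
draws — mimicking reserves spread across a region; pairwise separation is
enforced (default 40 cells, > 2× the maximum radius). All randomness flows
from one integer seed through fixed offsets, so outputs are byte-identical
across runs and platforms.

The standard fixture (`two-valleys-six-patches`, 200×200 at 30 m, noise
5 m ≈ 2% of the ~300 m relief) supports the parameter-recovery check:
extracted streams overlap the planted centrelines with tolerance-aware
Jaccard ≥ 0.7. That overlap measure is
`J_t = |dil(A,t) ∩ dil(B,t) ∩ (A∪B)| / |A∪B|` with t = 2 cells — it
reduces to plain Jaccard at t = 0 and forgives the one-to-two-cell
discretization offset that would drive the plain index of two thin lines
toward zero, while still penalizing unmatched feature cells.

What passing these fixtures does **not** show: real terrain has dissection
at all scales, flats, and braided channels the generator lacks; real
land-use maps are not elevation-banded; real reserves are not discs. The
fixtures validate the operators and their composition, not the ecological
realism of any particular resistance table, which remains the user's
domain judgment.

## Numerical choices and degenerate inputs

* Fill ε = 1e-6 × cell size; filling is idempotent to < 1e-12.
* All tie-breaks (D8 neighbour order, Dijkstra path length/index order,
  selection ordering) are fixed and documented, so identical inputs give
  identical outputs.
* Stream threshold above the maximum accumulation yields an empty network
  with a warning, not an error; an empty candidate network short-circuits
  scenario generation and is flagged in the run report.
* `dPC` with PC = 0, normalization of all-zero vectors, α/γ with v ≤ 2 and
  CR with d = 0 raise errors naming the undefined quantity.
* Pipeline problem sizes: the standard fixture keeps a full run (seven
  stages, 15 all-pairs corridors, four scenarios, node detection) around a
  few seconds on one core; the generator scales linearly in cell count.

## Known limitations

* Single-flow-direction (D8) routing only; no D∞ or multiple-flow models.
* One corridor per patch pair; corridor width is not modelled.
* `p_ij` removal in dPC does not re-route maximum-product paths around the
  removed patch (the matrix is treated as the connectivity model).
* The scenario grid is a heuristic exploration, not an optimization; the
  composite ranking intentionally favours link-rich scenarios and should
  be overridden when cost efficiency matters more than connectivity.
* No coordinate reference system handling or reprojection.
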