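# Methods

This note documents the models, conventions and numerical choices
behind `seedmorph`, in the order data flows through the pipeline.

## Cell geometry

Cells are simple polygons in µm, stored counter-clockwise (reoriented
on ingest, with closing duplicates and zero-length edges removed;
self-intersecting outlines are rejected via shapely validity).  Area
and perimeter are shoelace/edge-sum closed forms on the vertex loop.

**Roundness.**  Default is isoperimetric circularity 4πA/P², bounded
in (0, 1], resolution-robust, and exactly π/4 for a square.  Because
different labs use "roundness" for different statistics, an
ellipse-based variant (minor:major axis ratio of the area-moment
equivalent ellipse) is exposed via `roundness(..., method="ellipse")`.
The two orderings agree for near-rectangular cells but are not
numerically interchangeable.

**Growth polarity.**  GP = ½(P/L − 2) with L the caliper extent along
the local layer tangent.  For an a×L rectangle GP = a/L exactly, which
is the property the statistic is built on; for non-rectangular cells it
is a rectangle-model approximation of the anticlinal:periclinal ratio.
The model degenerates when P ≤ 2L (possible for discretised round
cells); GP ≤ 0 is then still returned, with a `DegenerateShapeWarning`
and a boolean flag in morphometry tables, rather than an exception —
downstream profile statistics are robust to occasional such cells and a
hard failure would discard the whole specimen.

## Layer tracing

The layer axis is the polyline of cell centroids (not a boundary
skeleton): cheap, stable at the cell counts involved (tens of cells
per layer), and exact for chains of rectangles.  Its known limitation
is very irregular or strongly interdigitated cells, where centroid
order may not follow the wall topology.

Cells are chained by polygon-clearance adjacency (contact tolerance
0.5 µm by default, absorbing segmentation pixelation).  A cell with
three or more neighbours raises an ambiguous-topology error.  Chains
broken by genuine gaps are bridged greedily through nearest chain
endpoints; when two or more multi-cell fragments exist, a proximal
`start_hint` (a chalaza-side point, supplied in the manifest) is
required to fix the orientation.  Without any hint, the proximal end
defaults to the lexicographically smaller endpoint centroid — an
arbitrary but deterministic convention.

Normalised position `s` is cumulative polyline arc length (0 at the
proximal end, 1 at the distal end).  Tangents are central differences
of the polyline (one-sided at the ends).  Note that the polyline spans
centroid-to-centroid, so roughly half a cell of physical length at
each end is outside the parametrisation; on a 60-cell semicircle this
makes the traced length ~1.7% short of the true arc.

**Regions.**  Chalazal / curving zone / micropylar are assigned by two
axis fractions, default (1/3, 2/3) — the source analyses do not
quantify the boundary placement, so it is configuration, not biology.
Assignment is half-open and distal-inclusive (s = b belongs to the
distal region), and the same tie-break is used everywhere positions
meet interval boundaries.

**Gaps.**  For each consecutive pair, gap = max(0, clearance −
contact_tol), clearance being the minimum polygon-to-polygon distance,
placed on the midline centred between the two cells.  The gap fraction
is total gap length over midline length of the inspected s-interval.
Because the tolerance is subtracted from every true gap, exact-recovery
benchmarks are run with zero vertex noise and contact_tol = 0; under
those conditions injected gap fractions are recovered to machine
precision on straight layers, and to within a few thousandths on arcs
(where the minimum distance between tilted neighbouring quadrilaterals
slightly undercuts the removed arc length).

**Layer summaries.**  Length is midline arc length over the mask
interval; a cell is counted when its occupied s-interval (between
midpoints to its neighbours) intersects the closed mask interval, so a
cell sitting exactly on the mask boundary is included.  The
"gynobasal" side defaults to s ∈ [0, 0.5]; whether that split should
be at the midline or at an anatomical landmark is dataset-dependent,
hence configurable.

## Profiles and per-position statistics

Per-cell measurements are treated as step functions of s — cells are
discrete objects, so piecewise-constant sampling is used rather than
interpolation between cell values.  Each cell occupies the interval
between the midpoints to its neighbours; profiles sample N positions
j/(N−1) including both endpoints (N = 67 within-genotype region
profiles, N = 201 genotype comparisons, following the figure
conventions of the analyses this package reproduces).  Positions
strictly inside a detected gap are treated as missing for that
specimen and dropped from that position's sample, with per-position n
reported.

Group statistics are arithmetic mean and sample SD (n−1) over
specimens: the per-position sample is one value per specimen, not
pooled cells, so n equals the number of seeds — matching how group
sizes are quoted in this literature.

Two groups are compared per position with the classical
pooled-variance two-tailed Student's t-test (the Welch variant is a
flag).  Degenerate positions: zero pooled variance with equal means
gives t = 0, p = 1; with unequal means t = ±∞, p = 0, flagged.  No
multiple-testing correction is applied by default, matching the
per-point testing convention of the source figures;
Benjamini–Hochberg is available behind a flag.  Significance is tiered
at 0.05 / 0.001 / 10⁻⁵ and maximal contiguous runs are reported per
tier; tier position sets are nested by construction.  Region
comparisons re-parametrise each region onto its own [0, 1] sub-axis
before resampling, then run the same machinery pairwise among the
three regions of one group.

## Synthetic tissue generator

The generator emulates the structure the pipeline measures, not the
imaging process: quadrilateral cells (rectangle model + Gaussian corner
noise) laid along a straight or circular-arc midline.  This matches
the rectangle approximation underlying GP and yields analytic ground
truth per cell; a Voronoi/organic-tessellation mode is a non-goal.
What it therefore does not emulate: curved cell walls, segmentation
errors, wall-thickness variation, out-of-plane effects of sectioning.
Passing tests show the measurement chain is correct on its own model
class, not that segmentation of real images is accurate.

Default study conditions (chosen once to mirror the targeted study
design and kept fixed): two groups of 33 and 20 specimens; an
endothelium-like layer of 60 cells on an arc of radius 130 µm whose
length emerges from its cells (~550–650 µm, under a full turn); cell
area ramping 40→90 µm² and aspect 0.85→0.55 proximal→distal (smaller,
rounder chalazal cells; larger, periclinally elongated distal cells);
per-cell lognormal CV 0.08, corner noise 0.15 µm, orientation jitter
0.03 rad; per-specimen lognormal scales (CV 0.10 area, 0.06 aspect)
for biological replicate variation.  The mutant-like effect enlarges
areas 1.3× and overrides aspect to 1.5 on s ∈ [0.75, 0.95], pushing
GP across 1 in a micropylar sub-domain.  An optional ii1'-like layer
(45 cells, aspect 0.5) carries injected gaps, default 4.6% of the
chalazal third in the mutant group — the scale reported for the
corresponding phenotype.

Gaps are implemented as removed arc length between consecutive cells
(cells are never deleted), solved so that the removed length over the
realised region length equals the target exactly in centroid-polyline
coordinates; gap sites are drawn at least 5% of the region width away
from the region edges so realised gaps stay inside it.  When a fixed
`arc_span` is requested, cells are similarity-rescaled to fill it
exactly (areas scale quadratically, aspect unchanged).

Determinism: one root seed; each specimen's RNG stream derives from
(seed, group index, specimen index, layer tag via CRC32), so growing
the cohort never reshuffles earlier specimens, and string hashing
randomisation cannot leak in.

`shrink_cells` insets polygons by half a wall thickness; rasterisation
round trips use it because abutting cells otherwise compete for shared
boundary pixels, which is also the realistic geometry of wall-stained
label masks.

## Raster path

`render_label_image` rasterises at a given µm/px with pixel-centre
convention and image y down mapped to Cartesian y up; overlaps are won
by the later cell with a warning.  `ingest_label_image` traces each
label at the 0.5 iso-level (sub-pixel marching squares on the padded
binary mask), simplifies at 0.25 px tolerance, and splits
multi-component labels with suffixed ids and a warning.  At 20 px/µm
the round trip recovers cell counts exactly and areas to well under
1% on wall-separated layers.

## Problem sizes and benchmarks

The shipped validation suite uses: 1000 random rectangles for the GP
identity; 100 random star polygons at 0.01 µm/px for the area oracle;
a 60-cell semicircle (R = 100 µm) for tracing; 20 replicate 50-cell
layers per injected gap level {0, 4.6%, 10%}; 200 replicate Gaussian
null cohorts (33 vs 20 specimens, N = 201) for type-I calibration;
full synthetic cohorts at 33 vs 20 for effect recovery (Jaccard of the
strongest-tier run against the injected interval) and for region
profiling at N = 67; 20 layers for the raster round trip; and a small
7-specimen cohort run twice for byte-level determinism.  These sizes
give stable statistics while keeping the whole validation in the
tens-of-seconds range.

## Known limitations

* The centroid-polyline axis underestimates physical layer length by
  half a cell per end and is unsuitable for lobed or interdigitated
  cells.
* GP is meaningful only under the rectangle approximation; strongly
  curved (banana-shaped) cells violate it.
* Per-position tests are independent across positions by design
  (matching the source convention); neighbouring positions share cells,
  so significant-run lengths on null data are more variable than
  independent-test intuition suggests.  Spatially correlated modelling
  is out of scope.
* The generator's group effects are piecewise overrides of smooth
  fields; transition cells at sub-domain edges blur detected run
  boundaries by about one cell width.
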