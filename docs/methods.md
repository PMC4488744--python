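# Methods

`fragscape` analyses the fragmentation of a focal land-cover class (the
motivating case is farmland mapped from classified satellite imagery at
30 m / 0.09 ha cells) through four connected stages: morphological
segmentation of the binary map, class-level pattern indices, a Markov chain
over the structural classes of successive dates, and tabular change/driver
statistics. This note records the models, the parameter choices, and the
places where the design was genuinely open.

## Structural segmentation

A landscape is a rectangular grid of foreground/background cells,
`(row, col)` addressed, row 0 at the top. Two parameters control the
segmentation:

* **edge width `D`** (cells): the morphological buffer distance,
  `D = sqrt(a^2 + b^2)` for axis offsets `a`, `b`. Default `D = 4`
  (120 m at 30 m cells). Distances are Euclidean, center to center.
* **connectivity `R`** in {4, 8}: the foreground adjacency rule, default 8.
  The background always uses the dual rule (8-connected foreground with
  4-connected background), which avoids the topological paradox of a
  diagonal ring both enclosing and not enclosing its interior.

Every foreground cell receives exactly one of seven labels, resolved in the
order core > islet > bridge > loop > perforation > edge > branch:

1. **core** — distance to the nearest background cell strictly greater
   than `D` (a map with no background at all is all core, with the
   distance-to-background taken as infinite).
2. **islet** — member of a foreground component containing no core.
3. **bridge** — lies on a shortest geodesic path, through non-core
   foreground, joining two distinct core components. Operationally: with
   `d_A(c)` the breadth-first distance from the contact cells of core
   component A (contact cells have `d_A = 1`), `c` is on a shortest A–B
   path iff `d_A(c) + d_B(c) - 1` equals the minimum of that sum.
4. **loop** — lies on a re-entrant corridor that rejoins the same core
   component. A corridor that leaves core and re-enters it encloses
   background that the core alone does not enclose; we call a foreground
   hole not contained in a hole of the core mask an *extra hole*, and
   classify a non-core cell as loop iff deleting that single cell reduces
   the extra-hole count. A naive "minimal path joining the same core
   through two distinct contact cells" rule is degenerate — any two
   adjacent core-adjacent cells satisfy it, which would absorb the whole
   edge band into loop — so the hole-based criterion is the package's
   definition. It captures unit-width re-entrant corridors exactly; wider
   re-entrant structures (where no single cell is essential) fall through
   to the boundary classes. Only cells background-adjacent to an extra hole
   need testing: deleting a foreground cell can only merge the complement
   components it is background-adjacent to, and the count can only drop
   through such a merge.
5. **perforation** — within `D` (Euclidean) of a core cell, with the
   strictly nearest background cell inside a hole (background enclosed by
   foreground, i.e. its background component does not touch the map
   border): the inner boundary. Ties between a hole and the open
   background resolve to edge.
6. **edge** — within `D` of core, facing open background: the outer
   boundary.
7. **branch** — whatever remains (one-ended stubs, and the corners of
   convex patches whose Euclidean distance to core exceeds `D` even though
   they are geodesically attached — a literal-definition consequence we
   keep deliberately).

Connectors are resolved *before* the boundary band so corridors shorter
than `2D` remain detectable; `segment(..., boundary_over_connector=True)`
flips that order for compatibility with tools that buffer the boundary
first.

The production path uses the exact Euclidean distance transform, labelled
components and multi-source Dijkstra on the non-core adjacency graph; the
test suite re-derives every label with an independent brute-force
classifier (exhaustive pairwise distances, explicit flood fills and BFS)
and checks cell-for-cell agreement on hundreds of random and geometric
maps. Because boundary membership compares `sqrt` of integers against
`sqrt` of integers, strict/non-strict comparisons are exact in floating
point at any realistic map size.

## Pattern indices

Class-level indices follow the standard raster formulations, with patch
areas `a_j` and perimeters `p_j` tallied in cell units and converted only
at the reporting boundary. Perimeters count cell edges adjoining other
classes *or the map border*, making them translation invariant; patch
adjacency defaults to 8 to match the segmentation.

* **PD** = `n / A * 100` patches per 100 ha (a per-km² variant is
  available).
* **NLSI** = `(e - e_min) / (e_max - e_min)` clamped to [0, 1], where `e`
  is the total class edge, `e_min` the integer-square minimum
  (`4n`, `4n+2`, `4n+4` around `n = floor(sqrt(a))`; equal to
  `2*ceil(2*sqrt(a))`, verified against exhaustive polyomino enumeration in
  the tests), and `e_max = 4a` while the class can be fully dispersed
  (up to half the grid); above that the complement is dispersed instead and
  `e_max = 4a - 2*max(0, E - 4(Z - a))` with `E` the grid's internal
  adjacency count. The boundary-effect correction for a complement forced
  onto border cells is ignored, which only matters for classes just above
  half coverage; NLSI is clamped and defined as 0 when the class fills the
  landscape.
* **COHESION** = `[1 - sum(p_j) / sum(p_j sqrt(a_j))] / [1 - 1/sqrt(Z)] * 100`,
  0 when all patches are single cells, 100 when one patch fills the
  landscape. Note it depends on the landscape cell count `Z` through the
  correction factor, so padding a map changes it by construction.
* **MESH** = `sum(a_j^2) / A` in hectares.
* **CONTAG** = `[1 + sum_ik q_ik ln q_ik / (2 ln m)] * 100` with
  `q_ik = P_i g_ik / sum_k g_ik`, rook adjacencies double-counted. Two
  consequences worth stating because they are often mis-remembered: a
  two-class checkerboard gives 50 (not 0), and two solid half-planes at
  P = (0.5, 0.5) approach 50 from below — with `m = 2` the value 100 is
  attainable only in the single-class limit. Observed farmland maps with
  contagion 47–50 at F = 0.49–0.65 therefore sit essentially at the
  two-class aggregation ceiling, which is what the synthetic generator is
  calibrated to.

Directionality: hole punching and corridor carving raise PD and lower MESH
and COHESION; removing whole small patches is *not* a fragmenting edit in
this sense (it lowers the patch count and can raise COHESION by deleting
the smallest patches), and the tests treat it accordingly.

## Synthetic landscapes

No classified imagery is distributed, so a modified-random-clusters neutral
model stands in for it: cells are marked with probability `cluster_p`,
marked clusters (4-connected) are assigned wholesale to the foreground in
random order until the target proportion F is reached, unassigned cells
take the majority class of their 8-neighborhood (ties and isolated cells
resolve by a Bernoulli draw at F), and a final pass flips random
class-boundary cells until the realized proportion is within 0.5 % of the
target (grids below ~50 cells cannot honour sensible targets and raise).
All randomness flows through one seeded generator; identical parameters are
bit-reproducible.

Single-scale clustering saturates near contagion 43 at F = 0.55, short of
the observed 47–50 band, so the generator also exposes a feature `scale`
(clusters grown on an `n/scale` grid and block-upsampled) and `smooth`
(3×3 majority passes). The calibrated setting
`cluster_p = 0.5, scale = 8, smooth = 1` reaches contagion ≈ 47.2 at
F = 0.55 on 256² grids and is what the demo scenario uses. Contagion is
monotone in `cluster_p` at fixed F over the sub-critical range.

What the generator does *not* emulate: multi-class land-cover context
(contagion here is computed on the binary map), anisotropic field shapes,
road/river corridors, and spatially autocorrelated *loss* (the change
scenarios below are spatially random given their kinds). Passing tests
therefore demonstrate correctness of the measurement pipeline and the
qualitative response to fragmentation, not magnitudes on real maps.

Change scenarios apply ordered loss-only edits — edge erosion, hole
punching, small-patch removal, corridor carving — each with a rate in
[0, 1] and all driven by one seed; foreground never grows (conversions
from background to the focal class are not modelled, matching their
observed rarity). `degrade_to_target` composes these edits with per-pass
budgets tied to the remaining deficit to land on a prescribed foreground
proportion.

The geometric fixtures (solid square, donut, dumbbell, ring-with-handle,
scatter, two-cores-with-stub) are built alongside a ground-truth label grid
computed by a literal-definition classifier kept in the same module; the
test oracle re-derives the same grids independently.

## Markov chain over structural classes

Per-cell transitions between two co-registered class maps are tallied over
the fixed 8-state space (seven classes + non-farmland background). Rows of
states absent at the first date become identity (absorbing) rows with a
warning — keeping P stochastic without inventing flow. Diagnostics:

* stationary distribution π (left eigenvector for the dominant eigenvalue;
  reducible chains return one valid π with a warning);
* convergence rate `rho = 1 / |lambda_2|`, `+inf` for one-step convergence,
  1 with a warning when `|lambda_2| = 1`; larger rho means faster approach
  to π;
* normalized entropy `H(P) = -sum_i w_i sum_j P_ij ln P_ij / ln s` in
  [0, 1]. The default weighting is the stationary one (the chain's entropy
  rate, `s` = states with stationary mass). In loss-only scenarios the
  background state is absorbing, π collapses onto it and the entropy rate
  is 0; a `weights="uniform"` row-average (`s` = all states) is provided
  and reported alongside, and is the more informative diagnostic for such
  chains. Which of the two a given published value used cannot always be
  determined; both are first-class here.

A parameter-recovery test simulates 100 000 per-cell transitions from a
known 8-state matrix and requires entrywise recovery within 0.01 and
rho/H within 2 %.

## Change and driver statistics

Per-interval annual change uses the interval-start denominator:
`rate = (area_2 - area_1) / (t_2 - t_1) / area_1 * 100`, losses negative.
Internals stay at full precision; the reporting boundary scrubs float error
at 1e-8 and rounds with ties toward zero, the convention under which the
published per-interval table is reproduced digit for digit from its own
printed inputs (its single exact tie, -193.095, prints as -193.09).

Pearson correlations between factor and response series report r, the
two-tailed p from the t distribution with n-2 df, per-pair n and
0.05/0.01 flags; zero-variance series yield r = NaN (not 0), and a masking
option blanks non-significant entries the way printed tables do.
Confusion-matrix accuracy reports overall accuracy and Cohen's kappa
(`kappa = (p_o - p_e) / (1 - p_e)`), with the degenerate `p_e = 1` case an
error.

## Pipeline and problem sizes

`run_pipeline` sequences reading → binarization → segmentation → indices →
per-pair chains → change statistics, writing CSVs, class maps, a log and a
JSON manifest (parameters, seed, input hashes, version) sufficient to
reproduce a report exactly. The demo scenario uses three 256² maps at the
calibrated aggregation with foreground proportions 0.6456 → 0.5909 →
0.4910; 256² keeps a full demo run in seconds while leaving hundreds of
patches for the indices. The brute-force oracle comparisons run on 40²
maps, where exhaustive pairwise distance computation is still cheap, with
200 random maps giving both connector classes non-trivial frequencies.

## Known limitations

* Loop detection targets unit-width re-entrant corridors; a two-cell-thick
  handle has no single essential cell and is classified as boundary/branch.
* Bridge cells are confined to *shortest* inter-core geodesics; a second,
  longer corridor between the same pair of cores is labelled branch, not
  bridge.
* NLSI's `e_max` above half coverage ignores border-degree corrections.
* The generator's contagion calibration is to the binary map; contagion of
  a full multi-class land-use mosaic is a different (lower-normalized)
  quantity.
* No georeferencing: rasters are plain grids; ASCII-grid headers and a
  JSON cell-size tag in TIFF are the only metadata read or written.
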