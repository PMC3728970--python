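# Methods

## Cost model

Movement is modelled on the 8-connected graph over a square grid of
resistance values r ≥ 1 (dimensionless rate, 1 = habitat). A step from
cell a to neighbour b costs ((r_a + r_b)/2)·d(a,b) with d = cell size
for rook moves and cell size·√2 for diagonal moves. Costs therefore
carry units of resistance × metres ("cost units"); 1 cost unit = 1 m at
resistance 1, which fixes the exchange rate used throughout: an 8 km
maximum dispersal distance becomes an 8000 cost-unit network threshold,
and a 40 m buffer in resistance-40 matrix becomes the 1600 cost-unit
corridor margin.

The neighbourhood, the arithmetic-mean step resistance and the √2
diagonal metric are the standard GIS cost-distance contract; they are
declared here rather than inferred, since alternative conventions
(knight's moves, geometric-mean blending) exist. Accumulated-cost
solves use Dijkstra (scipy's sparse-graph implementation) with
multi-cell source sets at cost 0; path backtrace walks downhill on the
accumulated-cost grid choosing, at each cell, the neighbour minimising
cost(b) + step(b, cur), ties broken in the fixed order N, NE, E, SE, S,
SW, W, NW, which makes paths bit-reproducible. Unreachable cells hold
+∞ (serialized as NoData). By default there are no absolute barriers —
buildings and rock (resistance 1000) are traversable at extreme cost,
matching a finite-valued resistance table — but a barrier threshold can
be configured.

Patch-to-patch paths treat whole patches as source and target (cost 0
inside both), so the reported route connects patch boundaries rather
than centroids. Where several boundary cells tie, the lowest-index cell
in row-major order is chosen (the argmin of the masked cost grid),
again deterministic.

## The three landscape models

- **Network (LCN):** habitat ∪ {cells with accumulated cost from the
  habitat set ≤ max dispersal × habitat resistance}. Monotone in the
  threshold by construction.
- **Buffered paths (LCP):** for every unordered pair of *visited*
  patches, the least-cost traverse; the mask is the union of Euclidean
  buffers (default 40 m) around the path polylines. Buffering happens
  in vector space on the polyline and the polygon is rasterized by
  cell-centre test, avoiding double discretization error. A zero
  buffer degenerates to the path cells themselves. Unreachable pairs
  are skipped with a warning and recorded on the result.
- **Corridor (LCC):** per pair, {x : cost_A(x) + cost_B(x) ≤ pair
  minimum + margin}, unioned over pairs and with the visited habitat
  itself included. Thresholding is per pair against that pair's own
  optimum, not against a global level. The lowest-fraction variant
  (keep the lowest q-quantile of each pair surface) is provided for
  comparison only.

## Movement segmentation

Fix density is a plain neighbour count within a radius (default 30 m).
A cluster is a maximal consecutive run of fixes with density ≥ the
threshold (default 5) whose strict majority lies inside one habitat
patch; the majority vote absorbs GPS scatter just outside the canopy.
The defaults are chosen so that a 15-minute dwell at the 3-minute
nominal interval can form a cluster. A movement runs from the last fix
of one cluster to the first fix of the next; its Euclidean length is
the straight line between those two fixes, its path length the sum of
consecutive-fix distances (a lower bound on the true path, since missed
fixes straighten the polyline).

Fix bookkeeping: the expected fix count over a movement of duration
T minutes is round(T/3) (half-up); the success percentage divides the
recorded count by the *unrounded* expectation T/3 and is capped at
100%, since a duration that is not a multiple of the interval can
record one fix more than its nominal expectation. This pair of rules
reproduces the recorded movement table exactly, including its
apparently inconsistent rows (e.g. 16 fixes in 80 min → expected 27 but
success 60.00%, and a 13-of-13 movement capped at 100.00%).

## Validation statistics

The comparison statistic divides the model's share of the convex-hull
area by its share of the movement points, both as percentages computed
on the raster (cells whose centre falls inside the hull). Full
precision is kept internally; the two-decimal display value truncates
toward zero, the convention under which the reported triples
(97/96 → 1.01, 42/81 → 0.51, 49/95 → 0.51) are self-consistent. A mask
containing no points yields an explicitly undefined statistic, not a
division error.

χ² goodness of fit scales availability weights to the observed total;
subdivided tests pit each group against the pooled rest (1 df each) and
are computed independently of the full-table statistic. The paired
t-test is two-sided on differences Euclidean − realised, so longer
realised paths give negative t. Mann–Whitney uses midrank ties and the
normal approximation with tie correction. No multiple-testing
correction is applied beyond the subdivided partition.

The breakpoint regression fits y = a + b₁x + b₂·max(0, x−c) by least
squares, with the breakpoint c searched exhaustively over observed
unique x values having at least two points strictly on each side —
exact and cheap at these sample sizes, and a noiseless two-segment
dataset is recovered exactly. The fit is continuous at the break; an
approximate F-test (2 extra parameters, screening only — the searched
break makes it anti-conservative) flags whether the break is supported.
RSS of the broken-stick fit never exceeds the single-line RSS because
the candidate set includes fits arbitrarily close to linear.

## Synthetic data

The landscape generator emulates a fragmented lowland-farmland site on
2 m cells (chosen so the 4 m field edges stay ≥ 2 cells wide after
rasterization): a 10.88 ha source wood and a 0.45 ha release wood
500 m apart, extra scattered woods, field-edge lines on a ~200 m grid,
a meandering river, a road verge and a farm track, in an
improved/arable/amenity matrix; all categories come from the bundled
21-category resistance table. Patch placement is rejection sampling
with a 30 m separation gap; the requested patch areas are honoured to
the cell.

The track simulator alternates woodland dwells (default 45 min,
stationary with 8 m jitter) with matrix transits between the release
and source woods. Transits are biased correlated random walks on 16
headings at a 30 s sub-step (0.35 m/s), scored by directional
persistence, goal bearing, local resistance, and the cover rule:
a penalty proportional to max(0, d_feat − min(d_hab, 40 m)). The cover
rule is the behavioural encoding of feature-guided matrix movement —
an animal keeps some refuge (habitat or a linear feature) within
reach, with 40 m as the comfort limit — and it is what imprints the
hinge in (distance-to-habitat, distance-to-feature) space that the
breakpoint regression recovers. Fixes are sampled every 180 s, dropped
with probability 0.55 under canopy and 0.05 in the open (reproducing
the wide spread of per-movement fix success), and perturbed by 3 m GPS
noise; the uncorrupted true path is returned alongside for oracle
checks. With persistence only (no goal, features or resistance bias)
the transit kernel reduces to a textbook correlated random walk, and
its mean squared displacement is checked against the closed form
E[R²] = l²·Σᵢⱼ c^|i−j|.

Two named walk regimes are used. The default spec is the
study-condition walk, calibrated once so that the simulated fix set
exhibits the ~40 m hinge with a positive left slope (weak resistance
weight 0.5, cover-rule weight 6). `WalkSpec.feature_biased()` is a
strongly cost- and feature-bound walker (resistance weight 4,
cover-rule weight 10, sharper choice) representing the regime in which
animals track the low-resistance network closely; under it the
buffered-path and corridor models score clearly below the network
model, which is the qualitative ordering the validation pipeline is
designed to detect. Demo and test problem sizes — a 1.2 km × 1.2 km
landscape, five animals × 6 h — are the package's own choices for a
desk-scale study.

What the generator does *not* emulate: real GPS error is spatially
autocorrelated and worse under canopy (here it is i.i.d. and
category-independent); real animals revisit ranges, interact and
disperse rather than shuttling between two woods; linear features are
straight or gently meandering rather than following field topology; and
fix failure is Bernoulli rather than satellite-geometry driven.
Passing tests therefore show the pipeline's logic is correct under the
stated movement model, not that any particular field system satisfies
that model.

## Numerical choices and degenerate inputs

- Resistance lookup is a hard error on any unmapped category (no silent
  default); the bundled table stores each category once and habitat
  categories must carry resistance exactly 1.
- Backtrace ties use a 1e-12 absolute slack; oracle comparisons use
  1e-9 relative tolerance.
- Empty feature sets make feature distances undefined (None), never 0.
- A degenerate constant corridor surface returns the whole surface with
  a warning in the lowest-fraction variant.
- Collinear point sets are rejected by the convex hull; zero-variance
  paired differences are rejected by the t-test.
- All stochastic operations take explicit integer seeds; the pipeline
  writes its full configuration (including seeds) to a provenance
  sidecar, and reruns are byte-identical.

## Known limitations

- The cost engine is isotropic; slope- or wind-aware costs are out of
  scope, as are circuit-theory (resistance-distance) models.
- The comparison statistic depends on the hull of the observed points
  and is undefined when no point falls in the mask; with few movements
  it is noisy.
- The breakpoint search assumes a single break; multiple regimes would
  need a different model.
- Pooling fixes across animals in the χ² tests pseudo-replicates; a
  per-animal stratified analysis can be built from the per-track
  outputs but is not the default.
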