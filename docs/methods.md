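# Methods

This note documents the models implemented in `locodist`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions made where the design was genuinely
open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Trajectories and ingestion

A trajectory is a uniformly sampled sequence of 2-D positions (mm) at a known
frame rate inside a rectangular arena, origin at the lower-left corner.
Internally everything is millimetres and seconds; ingestion converts from cm
or pixels (default 2.4 px/mm, the resolution of a typical tracking video)
once.  The kinematic operators assume a uniform frame grid, so ingestion
repairs the common defects of tracker output and counts every repair:

* duplicate time stamps are dropped;
* time stamps jittered more than 1 µs off the 1/fps grid are linearly
  resampled onto it;
* tracking dropouts of at most 5 frames are linearly interpolated — across
  longer gaps derivatives are meaningless, so they are an error unless the
  caller opts in;
* out-of-arena positions are clamped to the walls.

Analysis windows are half-open `[start, end)` so that contiguous protocol
windows partition a recording without overlap or double counting.

## Behavior curves

The behavior curve of a trajectory is the multivariate time series of its
per-frame behavioral factors, by default the speed and unsigned plane
curvature

    s(t) = sqrt(x'(t)^2 + y'(t)^2),
    kappa(t) = |x'(t) y''(t) - y'(t) x''(t)| / s(t)^3,

with derivatives by central differences on the frame grid (one-sided at the
ends, i.e. `numpy.gradient`), higher derivatives by repeated application.
In 2-D these are exactly the non-trivial entries of the Frenet-Serret frame
evolution; torsion is identically zero.

Positions are denoised first with a Savitzky-Golay filter.  The documented
default is order 5 with a 53-frame window, the setting appropriate for
20 fps video of steadily swimming fish; the parameter search
`select_smoothing_params` minimizes the product of the mean squared
positional deviation (fit) and the mean third-derivative magnitude
(roughness) over odd orders 1..7 and odd windows, with ties broken toward
the smaller order and window.  Objectives that are zero up to float noise
(signals a polynomial of that order reproduces exactly) are treated as
genuine ties, which keeps the documented tie-break meaningful on noiseless
fixtures.  Even orders are skipped: an even order behaves like the adjacent
odd one.  Orders above 7 are rejected as numerically unstable.

Frames slower than `speed_floor` (default 0.5 mm/s, about half the
displacement scale of the usual 3 mm/s immobility convention) get curvature
0 and a flag: kappa's s^3 denominator is meaningless for a stationary
animal.

Each factor is normalized by the logistic sigmoid
`sig(x) = 1/(1 + exp(-(x - mu)/sigma))` with mu and sigma the mean and
population standard deviation of that factor *over the analyzed window of
that subject*.  Consequences worth knowing:

* normalized values lie in (0, 1), so the alignment energy below is bounded
  by sqrt(|Theta|);
* BDD values are only comparable between equal-length protocol windows,
  because the normalization is per window;
* a constant factor maps to 0.5 everywhere (the limit of the centered
  argument).  "Constant" includes sigma below 1e-9 relative to the mean:
  rescaling pure float-representation noise of an exactly-constant signal to
  the full unit range would fabricate structure.

## BDD: alignment energy and its exact minimization

An alignment between two curves is a monotone correspondence hitting both
start and both end points; discretely, a lattice path from (0, 0) to
(n-1, m-1) with steps (1,0), (0,1), (1,1).  The energy of a path is the
*mean* per-step Euclidean distance between the matched samples — the mean,
not the total, because the continuous energy carries a 1/(u_f - u_0)
prefactor that normalizes by parameter length, and because without it the
sqrt(|Theta|) bound would not hold.  BDD is the minimum energy over all
paths.

Minimizing a mean over paths of different lengths is a fractional program,
not a plain shortest path: a path that adds cheap steps can lower its mean.
We solve it exactly with Dinkelbach iteration: repeatedly run a standard
O(nm) dynamic program on costs shifted by the current ratio lambda and
update lambda to the new path's mean; the iteration converges monotonically
(typically in 3-6 rounds) to the minimum-mean path.  The DP kernel is
numba-compiled.  Tie-breaks among equal-cost predecessors prefer the
diagonal, then (0,1), then (1,0); equal-energy optima are regarded as
equivalent, and only the energy is contract-bearing — the path is exposed
for visualization.  The test suite pins the implementation to a brute-force
enumeration of all monotone paths on small instances (exact agreement).

No warping-window (band) constraint is applied by default.

IIBDD, the self-distance, draws `n_pairs` pairs of equal-length
non-overlapping sub-intervals uniformly at random (rejection sampling on
overlap *within* each pair — mutual non-overlap of 1000 intervals in an
8-minute window is infeasible and is not intended), normalizes each segment
independently, and averages the pairwise BDD.  The segment length is a
required protocol parameter; IIBDD values are only comparable at equal
segment lengths.  Analyses of the bundled synthetic regimes use 20-second
segments, long enough to contain several freeze/dart cycles of the erratic
regime.

## Occupancy surfaces

The occupancy heat map is a histogram over an m x n grid of the arena
(default 20 x 12, about 1-cm cells for a 20 cm x 12 cm tank), normalized to
sum to 1 — occupancy *fractions*, which keep CSD comparable across window
lengths.  Cells are half-open with the right/top wall assigned to the last
cell.  Grids finer than the tracking resolution trigger a warning, not an
error.

The surface places one vertex per cell center plus a ring on the walls (ring
vertices carry the occupancy of their nearest cell, so a uniform map yields
an exactly planar surface), lifts each vertex to z = z_scale * rho, and
triangulates the planar points with our Bowyer-Watson implementation.  Since
the surface is a function graph, the planar projection is injective and a
2-D Delaunay triangulation of the vertex set is a valid surface
triangulation.  The default z scale makes the tallest peak 25% of the arena
diagonal; when two maps are compared, one shared scale (from their joint
maximum) is used so the comparison is symmetric.  The scale is exposed
because CSD depends on it.

The Bowyer-Watson triangulation is incremental with a fixed super-triangle
and insertion in input order, making the output deterministic; co-circular
ties (ubiquitous on grid points) are resolved by that order.  Predicates are
evaluated in unit-box-normalized coordinates with a 1e-9 relative in-circle
tolerance; the suite verifies the empty-circumcircle property by brute
force.

### Uniform remeshing

The circle-packing flattening approximates a conformal map best on meshes
with near-uniform edge lengths, so surfaces are remeshed before packing:
iteratively, interior edges much shorter than a fixed target length are
merged (never removing wall vertices), edges much longer are bisected (new
z by linear interpolation on the *input* surface, which remeshing treats as
ground truth), vertices slide in the plane under spring forces driving
interior 3-D edge lengths toward the target (wall vertices slide along
their wall, corners stay fixed), and the plane is re-triangulated.  The
loop stops when the max/min interior 3-D edge-length ratio is within
`1 + tol` (default tol 0.2) or an iteration cap, returning the best mesh
seen with a warning flag in the capped case.

The capped case is not an implementation deficiency but geometry: wall
edges are excluded from both the measure and the springs precisely so that
corner fans can keep short wall spacing (a 90-degree corner covered by
equal-length interior edges is impossible otherwise), yet triangulation
defects (5/7-valent vertices) still force a residual ±30% edge-length
spread on general spiky occupancy surfaces, and needle-like immobility
peaks add anisotropy that isotropic planar Delaunay cannot absorb.  On
near-lattice inputs the tolerance band is genuinely reached (tested); on
trajectory-derived maps the remesher typically converges to ratios of
1.6-1.9 and flags the cap.  Packing and CSD are well-defined either way;
uniformity only improves the conformal approximation.

## Circle packing

The flattening follows the Collins-Stephenson scheme: find radii for which
every interior vertex's angle sum (from the tangent-circle triangle fan) is
2 pi, then lay the circles out.  We solve the radii in the hyperbolic metric
of the unit disk, which is what makes "maximal" packings — boundary circles
internally tangent to the unit circle — natural: boundary circles get a
fixed large hyperbolic radius (12; e^-24 ≈ 4e-11 sets the distance of their
rims from the unit circle), and interior radii are iterated by a vectorized
Jacobi-Newton on the exact angle sums to a residual of 1e-10.  Angles are
computed with the half-angle form

    alpha = 2 arcsin sqrt( u (1-v)(1-w) / ((1-uv)(1-uw)) ),   u = e^{-2r},

which stays accurate for the tiny angles at huge boundary radii; the
arccos law-of-cosines form loses six digits there.

Layout is breadth-first placement in the Poincare disk (Mobius transfer to
the origin, rotate by the computed angle, transfer back), pivoting each
placement on the smaller of the two placed circles — placement error scales
with sinh of the pivot-to-neighbor distance.  A final Gauss-Newton polish of
the Euclidean tangency system (all centers and radii, sparse LSQR steps)
removes the accumulated breadth-first error; the shipped contract checks —
interior angle sums within 1e-8 of 2 pi, tangency residuals within 1e-7 —
come out at machine precision (~1e-13) in practice, and the hexagonal-wheel
fixture reproduces its closed-form maximal packing (all radii 1/3) to
1e-11.

## Alignment and CSD

The surface centroid sent to the origin is the area-weighted centroid of the
flattened vertex positions, weights one third of the adjacent planar
triangle areas on the source surface — stable against mesh refinement.  The
remaining rotation is brute-forced on an even grid (default 360 angles, 1
degree; theta = 0 is on the grid, so self-alignment is exact).  Reflections
(orientation-reversing disk maps) are not searched.

Candidate maps f = f_B^{-1} ∘ rot_theta ∘ f_A transfer vertices by planar
point location in the other flattened triangulation plus barycentric
interpolation (matplotlib's trapezoid-map finder, all angles in one query).
Rotated points that land just outside the other layout's center polygon are
shrunk radially until located; these fallbacks are counted on the alignment
object.  E_sd uses 3-D edge lengths and 3-D triangle areas over interior
edges only, in both directions, which makes it exactly symmetric under
swapping the surfaces (the angle grid is closed under negation).

CSD discretizes the two integrals as vertex sums weighted by one third of
the adjacent *planar* triangle areas (consistent with the A_e/3 convention
in E_sd), interpolates the other surface's occupancy at the image points
barycentrically, and divides by twice the arena area.  With a frozen
alignment, CSD is exactly linear in a common scaling of both occupancy
fields (tested).  Self-distance is zero to machine precision.

Magnitudes depend on the grid, the z scale, the packing tolerance and the
angle grid, none of which have canonical values; CSD is therefore a
*relative* measure — compare values only across identical settings.

## Synthetic regimes

The generator produces correlated random walks: per frame, the heading turns
by a von Mises draw (optionally replaced, with some probability, by a
uniform angle — heavy-tailed darting), the step is a truncated-normal speed
draw over fps, walls reflect the step (conserving length) and an avoidance
rule turns headings back toward the interior inside a 5-mm margin, a Poisson
process starts exponential-length freezing bouts, and an optional attractor
pulls the heading.  Recorded positions get bounded isotropic jitter
(0.3 mm, below the 0.42-mm resolution of 2.4 px/mm video).  Identical seeds
give bitwise-identical trajectories; cohort seeds spawn deterministically
from a master seed.

Two presets bracket the behaviors of interest and are fixtures, not claims
about any species:

* `CRUISE` — steady swimming: speed 30 ± 3 mm/s, concentrated turning
  (kappa = 20), no freezing.  Long recordings cover the arena nearly
  uniformly.
* `ERRATIC` — alarmed-like swimming: speed 45 ± 35 mm/s, diffuse turning
  (kappa = 1) with 25% uniform darts, six 6-second freezing bouts per
  minute, and a corner attractor at (40, 30) mm.

The contrast is the lever behind every separation test: freezing and darting
push the sigmoid-normalized factors into their tails, so the erratic curves
have higher normalized variance, higher self-dissimilarity (IIBDD), and
higher pairwise BDD, while freezing hot spots concentrate the occupancy
surface and *lower* within-class CSD.  Synthetic-cohort analyses use
order-3/21-frame smoothing (a 1-second window at 20 fps): the default
53-frame window, appropriate for real tracking noise, flattens the
simulator's sub-second darts and with them the kinematic contrast.

What the generator does not emulate: depth (the real assay projects a 3-D
tank onto 2-D), posture, social context, water-column preferences,
stimulus-locked onset dynamics, and tracker identity switches.  Passing
tests show the measures behave as designed on motion with the assumed
statistical structure; they do not validate any biological claim.

## Statistics

The randomized-partition test samples equal splits of the cohort uniformly
(with replacement across samples; against C(36, 18) ≈ 9.1e9 candidate
splits, collisions among 1e5 draws are negligible), takes the mean
cross-subset distance as the null statistic, and reports the standard score
of the observed cross-class mean.  The p-value is the two-sided normal tail
2(1 - Phi(|z|)) of the sampled null — an empirical rank cannot resolve
tails below 1/n_samples — with the empirical rank reported alongside.  A
degenerate null (all distances equal) returns p = 1 with a flag.

The logistic classifier is a hand-rolled univariate IRLS fit: it exposes the
per-iteration log-likelihood trace (non-decreasing by step-halving) and a
complete-separation flag (coefficient blow-up or saturated fitted
probabilities), which off-the-shelf fitters do not surface; the test suite
cross-checks its coefficients against statsmodels to 1e-6.  Classification
uses the 0.5-probability rule and reports training accuracy only.  A
constant feature yields the intercept-only model (probabilities equal to the
class prevalence).

## Problem sizes

Cohort-level computations in the tests and the acceptance script use 18 + 18
subjects at 20 fps: 120-second recordings, 60-second windows for pairwise
BDD, 10 x 6 occupancy grids with 36-angle alignment for pairwise CSD, 25
IIBDD pairs per subject, and 2e4 partition-test samples.  These sizes give
stable orderings and standard scores (the partition z on the default cohort
is ~19, an order of magnitude past the z > 3 requirement) while keeping the
full pipeline around a minute on one CPU; all of them are ordinary function
arguments, so larger studies simply pass larger values.

## Known limitations

* BDD is not a metric: the triangle inequality can fail under time warping
  (self-distance and symmetry do hold and are asserted).
* CSD magnitudes are discretization-dependent (grid, z scale, packing
  tolerance, rotation grid); only comparisons at fixed settings are
  meaningful.
* The rotation search is exhaustive over a grid, not continuous; the
  reported optimum is the grid argmin (nested grids never worsen it, which
  is asserted).
* The remesher's tolerance band is unreachable on general spiky surfaces
  (see above); the capped path is flagged, not silent.
* Per-window sigmoid normalization makes BDD incomparable across windows of
  different lengths by design.
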