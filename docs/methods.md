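# Methods

## Forward model

The package treats tractogram filtering as a non-negative linear inverse
problem. For a grid of `n_v` voxels and a tractogram of `n_c` streamlines,
the operator `A` (rows = voxels, columns = streamlines) stores the exact
geometric length of each streamline inside each voxel it traverses,
divided by the voxel volume. The coefficient `x_j` attached to streamline
`j` is interpreted as its cross-sectional area in mm², so the prediction
`A x` is a dimensionless intra-axonal volume fraction per voxel and can be
compared directly with a fraction map estimated from diffusion MRI (e.g.
by SMT or NODDI on real data). Extra-axonal/hindered compartments are not
modelled; isotropic (free-water) columns are supported and exempt from
penalization, and are off by default in length mode.

In-voxel lengths are computed per linear segment by cutting the segment at
every voxel-boundary plane it crosses and attributing each piece to the
voxel containing its midpoint. Voxel boxes are half-open (a point on a
shared face belongs to the higher-index voxel), voxel indices are 0-based,
and a world point `p` maps to voxel `floor((p - origin)/voxel_size)`. No
resampling of streamlines is performed; traversal is exact for polylines.
The per-voxel lengths of a streamline sum to its in-grid arc length to
1e-9 relative tolerance (tested on 1000 random polylines).

A second row space — one row per (voxel, gradient direction) with stick
(anisotropic tensor) columns per streamline and ball columns per voxel —
implements the small teaching example below. Stick and ball diffusivities
default to 1.7e-3 and 3.0e-3 mm²/s at b = 3000 s/mm² with 30 near-uniform
directions; recovery of the example's coefficients is invariant to these
constants as long as the 7 columns remain identifiable.

## Estimation

* **NNLS** (`lambda = 0`): `min_{x>=0} ||Ax - y||²`.
* **Adaptive group lasso**: streamlines are grouped by the unordered pair
  of gray-matter ROIs they connect; the penalty `sum_g lambda_g ||x_g||₂`
  with `lambda_g = lambda |g| / ||x_g^NNLS||₂` drives whole bundles to
  zero. The cardinality factor is `|g|` exactly (a `sqrt_cardinality`
  variant exists but is not the default). Groups whose NNLS norm is zero
  receive an infinite weight and are eliminated before the solve — the
  unregularized fit already deems them unnecessary, and the adaptive
  weight is undefined there.
* **Lasso**: the singleton-group special case (per-streamline adaptive
  weights `lambda / x_i^NNLS`), kept as a comparison method.

The optimizer is an accelerated proximal gradient method (FISTA) with the
exact proximal operator of (non-negativity + group-L2): project the block
onto the non-negative orthant, then shrink its norm by the threshold,
zeroing the block when the projected norm does not exceed it. The step
size comes from a power-method estimate of `2||A||₂²` with a 1% safety
margin, doubled whenever the quadratic majorization test fails
(backtracking); on an objective increase the momentum is restarted at the
best iterate and a plain descent step is taken, so the objective trace is
non-increasing by construction. For pure NNLS the columns of `A` are
equilibrated to unit norm internally (an exact reparameterization); this
matters when column scales differ by orders of magnitude, as between
stick and ball columns. Initialization is `x = 0`; convergence is declared
after five consecutive relative objective drops below `tol` (default
1e-8) or `max_iter` (default 2000). Solutions are verified in the test
suite against scipy's active-set NNLS, an SLSQP constrained-QP oracle for
the prox, and SLSQP on small group-lasso instances.

Regularization paths are computed on an ascending lambda grid with warm
starts; the default 20-point grid is log-spaced over
`[1e-4 * lambda_max, lambda_max]`, where `lambda_max` is the smallest
global strength at which `x = 0` is stationary for every penalized group
(computed from the gradient at zero and the adaptive denominators). A
cold-start spot check in the tests confirms warm starting does not change
the solutions.

Streamlines whose endpoints cannot both be assigned to (distinct) ROIs
are excluded from the fit and reported with zero weight, keeping the
groups a true partition of the fitted columns; their count is reported.

## Endpoint assignment and connectomes

An endpoint inside a labeled voxel takes that label; otherwise it takes
the label of the nearest labeled voxel centre within the assignment
radius (default 2 mm, Euclidean world distance), ties broken toward the
lower label. Distance is measured to voxel centres because the
parcellation is volumetric. Self-connections are excluded. Connectomes
are symmetric with zero diagonal; edges with total weight at or below
1e-12 are treated as absent (solver float noise). Edge weights are either
streamline counts (raw tractograms) or sums of estimated streamline
weights (filtered tractograms). Network density is the fraction of the
`R(R-1)/2` possible pairs that carry an edge.

## Evaluation

Estimated edges present in the ground truth are valid bundles (VB),
others invalid (IB); sensitivity is `VB/P` with `P` the number of true
bundles and specificity `1 - IB/N` with `N` the number of negatives a
tracking procedure could produce. For generated phantoms `N` is the
number of ROI pairs reachable by the splicing mechanism (see below), not
all unconnected pairs: negatives that no tracking error could create
would inflate specificity. Youden's index `J = sensitivity +
specificity - 1` summarizes both. Edge-weight error normalizes each
connectome by its own maximum and takes the root of the sum of squared
differences over the upper triangle (double counting a symmetric matrix
would only scale the value by sqrt(2); a `triangle="full"` mode provides
that convention). An all-zero estimated connectome skips its
normalization and is compared as zeros. Printed-value comparisons round
half away from zero to the displayed precision.

Baselines: cardinality thresholding removes edges with streamline count
at or below `k` (swept over all observed counts), and random removal
deletes `floor(rate * n_bundles)` edges uniformly, averaged over repeats
with a fixed seed; its mean J matches the closed-form expectation in the
tests.

## Synthetic phantoms

The generator emulates the statistical situation of connectome-validation
phantoms: ground-truth bundles with known endpoints, a candidate
tractogram containing both true and false bundles, and a fraction map
that is exactly explainable by the true geometry.

* Grid: 20³ voxels of 1 mm by default. ROIs are spherical caps
  (radius 2 mm) centred on the grid boundary faces, rejection-sampled to a
  minimum separation; placement failure raises an explicit error.
* Bundles: cubic-spline centerlines (chord-length parameterized) from ROI
  centre to ROI centre through two control points near the grid centre —
  so bundles cross there, which is what makes false-positive construction
  possible. Radii are uniform in 1.5–4 mm; each bundle carries 12 fibers
  by default, each a constant perpendicular offset of the centerline
  within the radius, tapered to zero at the endpoints so fibers terminate
  at their ROI.
* Fraction map: accumulated from the exact fiber geometry (length ×
  cross-section / voxel volume) and scaled so its peak is 0.8, leaving
  headroom below the physical ceiling of 1; the per-fiber area implied by
  that scaling is stored, making noiseless parameter recovery testable to
  1e-4 (measured: ~1e-12). Optional additive Gaussian noise on the map is
  available but off by default — the fitted quantity here is the fraction
  map itself, and its noise model on real data depends on the upstream
  microstructure fit.
* Candidate tractograms: true streamlines re-trace each bundle with fresh
  offsets plus smooth low-frequency jitter (default amplitude 0.2 mm,
  a realistic tracking wobble that keeps endpoints well inside the 2 mm
  assignment radius). False streamlines splice the front of a fiber from
  one bundle onto the back of a fiber from a crossing bundle at their
  closest approach — the dominant mechanism by which tractography creates
  plausible-looking but wrong connections. Requested false bundles beyond
  the constructible set raise an error; the constructible count defines
  `N`.
* Everything is a pure function of (configuration, seed); identical seeds
  give bit-identical phantoms and tractograms.

What passing on these phantoms does *not* show: real tractograms contain
partial-volume and curvature-dependent biases, broken and truncated
streamlines, and fraction maps carry spatially correlated model error —
none of which the generator emulates. The phantoms isolate the
redundancy-resolution question (can the method tell apart true and
spliced bundles when the data admit an exact explanation?), not the full
difficulty of in vivo filtering.

## Problem sizes and experiment design

The standard experiment uses 12 ROIs, 6 true bundles (12 fibers each) and
6 spliced false bundles (8 streamlines each) on the 20³ grid, with a
20-point lambda grid — roughly 8000 rows by 130 columns, solved in a few
seconds. These sizes were chosen so the full sweep is comfortably
interactive while leaving the operator genuinely overcomplete (several
streamlines per voxel). At the default conditions the sweep recovers the
exact true support on most seeds; when it misses, a single false bundle
survives at every grid point, reflecting a splice that is nearly
collinear with a true bundle at this jitter level.

## Known limitations

* Only the intra-axonal compartment is modelled in length mode; data with
  substantial free-water contamination need the isotropic columns.
* Endpoint assignment uses voxel-centre distances; surface-based
  parcellations and dilation-based assignment are out of scope.
* At `lambda = 0` the sum-of-weights connectome can already lack edges
  that the raw streamline-count connectome has (NNLS may zero every
  streamline of a redundant bundle), so the first sweep row is the NNLS
  connectome's J, which is not necessarily the raw count-based J.
* The solver is a single-CPU dense-vector/sparse-matrix implementation
  aimed at phantom-scale problems, not at multi-million-streamline
  whole-brain tractograms.
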