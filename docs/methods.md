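# Methods

`ecm-comm` infers long-range mechanical communication between cells embedded
in fibrous extracellular matrix (ECM) by correlating temporal fluctuations of
local matrix density between candidate partners.  The package has two data
paths that share one analysis core:

1. a **mechanical simulation path** — contractile circular cells in random
   2D fiber networks, solved quasi-statically step by step; and
2. an **imaging path** — windowed intensity quantification of 3D
   confocal-style stacks in a coordinate frame aligned with the axis
   connecting a cell pair, fed by a synthetic stack generator that emulates
   the experimental situation.

## Fiber network model

Networks live in a square domain of halfwidth `h` (arbitrary units, AU).
Nodes are scattered by stratified (jittered-grid) sampling followed by one
damped (factor 0.5) centroidal-Voronoi relaxation step, then connected by
greedy candidate-edge insertion over nearest-neighbor candidates subject to
degree caps and a minimum inter-fiber angle, with relaxation passes that top
the mean connectivity up to its target.  Defaults: mean connectivity 8, cell
diameter 0.08 AU, mean fiber length 0.02 AU (a 4:1 cell-diameter to
fiber-length ratio), fiber thickness carried as metadata only.

Two generation choices deserve comment:

* **Homogeneity versus isotropy.**  A pure Poisson scatter yields a local
  fiber-density coefficient of variation of ~0.17 at the scale of a
  quantification window; density changes produced by realistic contraction
  are of order 5–30%, so that heterogeneity would drown the z-scored signal.
  Stratified sampling plus one damped relaxation step brings the window-scale
  CV to ~0.05 while the fiber-orientation histogram remains statistically
  uniform.  Stronger (undamped) relaxation was rejected: it develops local
  hexagonal order whose preferred directions fail the isotropy test.
* **Void carving by truncation.**  Cells are circular voids.  Fibers crossing
  a void are cut exactly at the perimeter (new nodes at the circle
  intersections, rest lengths shared proportionally), so matrix density is
  conserved up to the cell boundary and the carved network is stress-free at
  onset.  Deleting crossing fibers outright instead depletes the onset
  density adjacent to the cell by about one background standard deviation,
  which distorts every downstream densification measurement.  Nodes on the
  perimeter annulus (within 10% of the radius) form the cell's boundary-node
  set.

## Fiber mechanics

Fibers are linear truss elements joined at freely rotating hinges with a
piecewise tangent modulus typical of biopolymers: `E0` in the small-strain
band (−2% to +2%), `0.1·E0` under compression beyond −2% (buckling), and an
exponentially growing modulus under tension beyond +2% (strain stiffening),
`E(ε) = E0·exp(k(ε − 0.02))`.  The factor ten and the 2% thresholds are fixed
by the model description; the stiffening rate is not, so `k` defaults to 30
per unit strain — a characteristic stiffening strain of ~3.3%, the scale
reported for collagen and fibrin gels in quantitative fiber-network models —
and is exposed in `ConstitutiveParams`.  The rate matters: strain stiffening
is what carries force along tensile chains between distant cells, and much
softer stiffening (characteristic strain ≳10%) measurably weakens the
inter-cell correlation signal at pair distances beyond ~4 cell diameters.
A `linear_to_15pct` variant stays linear to 15% strain before stiffening.  Stress and energy density are the exact
integrals of the tangent modulus, so the energy is C1-continuous.

**Contraction protocol.**  Each step displaces every boundary node of a cell
radially toward the void center by that step's percentage of the *initial*
radius, along the node's original radial direction (50 steps of 1% therefore
accumulate to 50% of the radius).  Heterogeneous contraction draws each
cell's step independently from N(μ=1%, σ) with σ up to 0.75%; negative draws
are applied as drawn (small expansions) to preserve the stated distribution.
Leader–follower schedules implement
`follower(t) = (1−α)·N(μ,σ) + α·leader(t−1)` (first step independent) and the
amplified copy `follower(t) = β·leader(t−1)`, β ≥ 1.  Passive cells receive
no imposed displacement; their boundaries move only under network forces.
The outer rim is fixed throughout.

**Equilibrium solver.**  After each step the free nodes minimize total
elastic energy.  The implementation runs L-BFGS with the analytic gradient
from a cold start and then damped semismooth Newton iterations on the
assembled sparse tangent stiffness until the maximum nodal force residual is
below 1e-8 (AU force units).  The Newton stage exists because the energy is
C1 but not C2: quasi-Newton methods stall one to two orders of magnitude
above the target residual at the law's kinks, while Newton steps with a line
search and an LU factorization that is cached across iterations and across
contraction steps (refactored only when progress stalls) converge reliably
and fast.  Warm starts from the previous step make the per-step cost a few
factorizations at most.  Indefinite stiffness (possible with many buckled
fibers) falls back to the gradient direction.

## Density quantification (simulation path)

The quantification window is a square of one cell diameter.  Local fiber
"volume" is the length of each fiber clipped to the window, rescaled by the
fiber's onset-to-current length ratio (`inner(t)·L(t0)/L(t)`), which makes a
fully interior fiber count its onset length and conserves total material
under the 2D representation of buckling.

Background statistics are computed once, at onset, from windows tiled over
the domain at steps of 0.02 cell diameters per axis, excluding windows that
intersect the window centered on any cell.  The dense tiling is made cheap by
rasterizing the onset fiber length onto a grid of the tiling step and
box-summing with an integral image.  All densities are reported as z-scores
against this background.

**Window anchoring.**  The window's inner edge is tangent to the cell
boundary at the point facing the partner; window distance (in cell diameters)
shifts it along the connecting axis, perpendicular offsets are applied after
anchoring, and the placement is recomputed every frame as the boundary moves.
The boundary radius used for anchoring follows the cell's *linearized*
contraction trend rather than its instantaneous noisy radius: the density
gradient at the boundary is steep, so anchoring to the noisy radius injects
the cell's own contraction noise into the measurement through window motion
and roughly halves same-versus-different discrimination.  The linearized
anchor still tracks the contracting boundary (it is identical for noise-free
schedules); instantaneous and onset anchoring remain available as options.

Single cells average four windows (up, down, left, right).

## Imaging path

Physical points are (x, y, z) µm; voxels are (frame, Z, Y, X) with voxel
centers at `(i + 0.5)·voxel_size`.  For a pair of tracked centers the package
builds a rotated frame: the connecting axis; the Z axis as the projection of
the microscope's axial direction perpendicular to the connecting axis (for a
perfectly vertical pair, where that projection vanishes, the lateral x
direction is substituted — a convention of this package); and the XY axis
completing the right-handed triad.  Effective sampling resolutions mix
lateral and axial voxel sizes by the elevation angle θ:
`res_conn = θ/90·res_Z' + (90−θ)/90·res_XY'` and symmetrically for the new Z
axis.  Window means use trilinear interpolation on a sample grid at those
resolutions.  Frames are invalid when annotated artifactual, when strictly
more than 5% of sample points leave the imaged volume, or — for a pair —
when the two partner windows overlap each other (shared voxels would
correlate the series trivially).  A literal "window overlaps its own later
frames" rule was considered and rejected: windows of static or slowly
drifting cells always overlap their near-future positions, so that reading
invalidates essentially every frame of any realistic series.

**Normalization border.**  Each window is corrected by two flanking border
windows along the pair Z axis (height 0.5 cell diameter, gap 0.25, width one
cell).  Correction is subtraction in z-score space — equivalent to
`(window − border)/σ_bg` — which cancels additive locally shared intensity
components exactly; a ratio would be ill-defined around zero for z-scored
data.  If one border is unusable the other is used alone; if both fail the
frame is invalid.

**Synthetic stacks.**  The generator emulates: two bright Gaussian cell
bodies per pair; a static fibrous speckle background; an adjacent-ECM
densification field per cell that starts ~3 background SD above the mean
(pre-imaging remodeling) and grows over the acquisition; per-cell activity
fluctuations mixed from a private and a pair-shared component with weight
`coupling`; spatially smooth local background fluctuation modes shared by
nearby regions; a global illumination flicker; voxel shot noise; and a slow
random-walk drift of the cell centers.  Ground truth (tracks, partner map,
activity series) is returned alongside the stack.  What the generator does
*not* emulate: real fiber texture and its anisotropic remodeling, cell shape
and division, bleaching, or mechanical coupling mediated by an actual gel —
so passing imaging-path tests demonstrates the correctness and sensitivity of
the measurement pipeline, not biological validity on real data.

## Analysis core

Series are aligned on their longest run of frames valid in both partners
(minimum 15 frames at 15-minute resolution, 50 at 5-minute; 5 and 15 after
downsampling).  Detrending is temporal differencing: order 2 by default for
simulation series, order 1 for experimental-style series, or chosen
automatically by escalating until the KPSS test fails to reject stationarity
and the ADF test rejects non-stationarity, both at α = 0.05.  Correlation is
Pearson's r on the differenced series.

* **Same-versus-different** enumerates every ordered triplet of a
  communicating pair plus one cell from another communicating pair of the
  same experiment batch, and reports the fraction of triplets whose
  within-pair correlation exceeds the cross-pair one, with a Wilcoxon
  signed-rank test of the paired differences.
* **Real-versus-fake** places a cell-free "fake partner" on the circle whose
  radius is the true pair distance, at the angle maximizing the minimal
  distance to all other real cells (lateral plane through the real cell in
  3D), quantifies it identically, and compares real–real to real–fake
  correlations.
* **Matchmaking** correlates each cell against its true partner plus 49
  candidates resampled with repetition from the other cells of the
  experiment; the partner's position in the descending correlation list is
  its rank, ties resolved against the partner (worst rank).  The random
  baseline for rank 1 is 1/50 = 0.02.
* **Downsampling sensitivity** re-runs same-versus-different on every
  possible start offset of a subsampled series and pools the comparisons.
* **Leader–follower** scans Pearson correlation over integer lags; the
  argmax lag assigns the leader (ties across lags yield no call).

Correlations are never computed across experiment batches; within a
simulated batch, each communicating pair lives in its own network and
"different" cells come from other networks, mirroring the definition of
non-communicating pairs.

## Problem sizes and tolerances

The reference setting uses a 50-cell-diameter domain (halfwidth 2 AU).  The
package's standard batches are scaled down: pair simulations keep a rim
margin of 5–6 cell diameters beside each cell (several thousand nodes), and
single-cell runs a margin of 8; the acceptance script uses 12 pairs at pair
distance 4, 8 at distance 9, and 7 single cells.  Discrimination fractions
at these sizes carry sampling errors of a few percentage points, and the rim
proximity slightly damps long-distance transmission (distance-9
discrimination rises by ~4 points when the margin grows from 5 to 7
diameters).  Margins below ~4 diameters distort the statistics badly and are
used only where a check needs signal presence rather than calibrated values.

Known limitations: 2D mechanics stands in for 3D gels; cells are rigid
circular boundary conditions that do not respond to incoming forces; the
solver tolerance (1e-8) and stiffening rate are package choices where the
source description is silent; and the single-cell densification decay
measured on the integer window grid lands at 1 window distance (the first
window whose mean z drops below 1), one window short of the narrative figure
of ~2 cell diameters — consistent with that figure if it is read as distance
from the cell center rather than from the boundary.
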