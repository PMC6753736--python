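# Methods

`linacqa` evaluates, by simulation, how accurately a geometric quality-assurance
procedure for a radiotherapy linac C-arm can recover the machine's geometry
from EPID images of a two-module fiducial-ball phantom, given that the image
analysis locates each projected ball center only to within some uncertainty
sigma.  Everything the package computes derives from one model: perturb ideal
projections with Gaussian noise, re-estimate the geometry, repeat, and study
the dispersion of the estimates.

## Coordinate conventions

The room frame has its origin at the nominal isocenter, `Y` along the nominal
gantry rotation axis, `Z` along the local vertical (up), `X = Y x Z`.  At
gantry angle psi = 0 the source sits at `(0, 0, SAD)` and the beam points
along `-Z`; rotating the gantry by psi moves the source to
`(SAD sin psi, 0, SAD cos psi)`.  The collimator rotates about the
source-isocenter axis.  The detector plane is normal to the beam axis at SDD
beyond the source; its in-plane 2D frame co-rotates with the gantry but not
with the collimator, and its origin is the piercing point of the beam central
axis.  All lengths are cm, angles degrees; the localization noise sigma is
quoted in mm and applied in cm (factor 0.1, exact).  The sign/handedness of
the frame is a free convention — the error statistics are invariant to it.

## Forward model

* Machine constants: SAD 100 cm, SDD 180 cm (140 cm in the large-phantom
  configuration), square 20 cm x 20 cm radiation field.  All simulated
  machine states are exactly nominal: the Monte Carlo characterizes a
  correctly tuned device.
* Phantom: a table-mounted module (markers fixed in the room frame) and a
  collimator-head module (markers co-rotate with collimator, then gantry).
  Default modules: 6 balls in an 8 cm cube on the table, 4 balls in a 6 cm
  cube on the head, ball radius 3 mm.  Layout generators are deterministic:
  markers grouped in parallel planes perpendicular to the beam-facing axis
  (at most 4 per plane on the table, 3 on the head), every marker at a
  distinct gantry-axis coordinate, with a fixed low-discrepancy stagger.
  The stagger is not cosmetic: exactly regular marker spacing places the six
  table markers on a critical configuration of the camera-resection problem
  (the DLT system below acquires an extra null direction).
* The head module is mounted on the beam axis 35 cm above the isocenter
  (toward the source), a plausible accessory-mount position; published work
  on this phantom type does not pin the mounting distance, and the
  dispersion results are insensitive to it as long as the module volume is
  fixed and all markers stay inside the field cone.
* Each image record holds the noisy 2D projections of all marker centers and
  of the four field corners.  Noise is i.i.d. Gaussian per coordinate, the
  same sigma for markers and corners.  (Corner coordinates must be perturbed
  for field-geometry dispersions to depend on sigma at all; treating the
  corners as directly measured detector points is the simplest model
  consistent with that.)  Ball radius affects visibility/overlap checking
  only, not the projected center.
* Random numbers: every image draws from its own generator seeded by the
  tuple (experiment seed, replicate index, image index), so replicates can
  be evaluated in any order — or in parallel — with bit-identical results.

## Reconstruction chain

Per image (collimator angle theta, gantry angle psi):

1. **Camera resection.**  The table-module marker coordinates are known (in
   practice from coordinate-measurement metrology; exactly, in simulation).
   A pinhole camera — source position (3), detector orientation (3), focal
   length = SDD (1) — is fitted by damped least squares (Levenberg-Marquardt
   with Marquardt scaling) on the reprojection error.  The principal point
   is *fixed* at the detector 2D origin: EPID coordinates are referenced to
   the calibrated beam-central-axis piercing point.  This constraint
   matters: freeing the principal point roughly doubles the SAD/SDD error
   dispersion because source depth, focal length and principal point become
   jointly quasi-unidentifiable from a small marker cloud.
2. **Head-module pose.**  With the camera known, the rigid pose of the head
   module is fitted by full-perspective least squares over its 6 parameters.

Both refinements are started from the nominal machine state, which the QA
procedure knows (it commanded the angles).  A no-prior path exists and is
tested — closed-form DLT resection and POSIT pose initialization — but the
DLT is unreliable precisely for 6-marker two-plane layouts (near-critical
configuration), which is why the nominal start is the default.  Convergence:
relative cost decrease below 1e-10, at most 200 iterations; the candidate
step is rejected and the damping increased tenfold whenever the cost would
rise, so zero-noise data reproduce the exact geometry to machine precision.

Per gantry angle:

3. **Collimator axis.**  The reconstructed head-marker constellations at the
   different collimator angles are related by rotations about the collimator
   axis.  Each consecutive pair gives a rigid motion (Kabsch rotation +
   centroid translation); the axis direction is the extrinsic (chordal) mean
   of the per-pair rotation axes after hemisphere alignment, and the anchor
   point is the joint least-squares fixed point of all pairwise motions
   (minimum-norm solution of the stacked equations `(I - R_k) x = t_k`).

Globally:

4. **Isocenter** = the point minimizing the sum of squared distances to the
   per-gantry-angle collimator axes, in closed form via the normal equations
   of the summed projectors `sum_i (I - d_i d_i^T)`.
5. **Gantry axis** = extrinsic mean of the rotation axes between
   consecutive-gantry-angle point collections (head markers plus, by
   default, the resected source positions; table markers are excluded
   because they do not rotate).
6. **Gantry angle** = angle between the collimator axis (canonicalized to
   point from isocenter toward source) and the local vertical, signed by the
   X component; **SAD** = |(source - isocenter) . axis|; **SDD** = fitted
   focal length (= source-to-detector-plane distance).
7. **Field geometry.**  The four observed corner points are back-projected
   along their source rays onto the plane H normal to the collimator axis
   through the isocenter; edge lengths, corner angles and deviations from
   the nominal corners are read off in H.

## Error metrics and their pooling

Per replicate: `alpha` (gantry-angle error, one per gantry angle), `theta`
(gantry-axis direction error, one scalar, folded >= 0), `omega` and `L`
(field corner-angle and edge-length errors, four per image), `s` (three
isocenter components), `l = |s|`, `dsad`/`dsdd` (one per image —
single-measurement errors; their dispersion is therefore independent of how
many images the plan contains, matching how such tables are conventionally
reported).  Summaries are sample standard deviations about the sample mean,
pooled over replicates and within-replicate values, with chi-square 95%
confidence intervals computed on the pooled count (within-replicate values
are weakly correlated, so these intervals are mildly optimistic; at the
default >= 1000 replicates the half-width is below the +/-5% level quoted
for such studies).

The probabilistic test machinery is empirical: the tail probability of an
observed difference Delta_M is the fraction of null-model samples with
|Q_M - Q_N| >= Delta_M, and the tolerated difference Delta_TH for a chosen
tail probability Pr_TH is the (1 - Pr_TH) quantile of |Q_M - Q_N|.

## Numerical choices

* Geometric degeneracy threshold 1e-9 cm; condition-number cap 1e8 for the
  closest-point normal equations; both are double-precision headroom at cm
  scale.  Near-identity rotations (< 1e-6 rad) have no usable axis and are
  refused.
* Lines are unoriented; every axis-valued estimate is canonicalized to the
  hemisphere of a physically meaningful reference (toward the source, or +Y)
  before averaging or differencing.
* Three evenly spaced gantry angles over [-180, 180] degenerate to two
  physically coincident beam axes; the isocenter solver correctly refuses
  such plans.
* Replicates whose reconstruction fails are excluded and counted; more than
  1% failures aborts the experiment.  In the supported configuration ranges
  the failure count is zero.

## What the simulation does and does not capture

The generator emulates exactly the stated study conditions: nominal
geometry, Gaussian localization noise of 0.1-0.5 mm, the plan grids (gantry
[-180, 180], collimator [-165, 165]; the 5-collimator set is the
conventional (-165, -90, 0, 90, 165)), and the module size/count ranges.
It does not model detector pixelization, scatter, beam profiles, marker
detection from real images, mechanical sag, couch motion, or errors in the
phantom's own metrology.  Passing dispersions therefore quantify the noise
floor of the *reconstruction procedure*, not of a physical linac: on a real
machine they are a lower bound on observable test dispersion.

Two caveats for comparisons with published tables of this procedure family:
the gantry-axis angle dispersion reported here is noise-limited and
sigma-dependent, whereas published theta tables show a large
sigma-independent component intrinsic to a different (unpublished)
axis-averaging procedure; and this package's field-geometry (omega, L) and
isocenter dispersions come out *smaller* than published values at low
gantry-angle counts, consistent with the same intrinsic-variance difference.
Where the reconstruction model is pinned down by the published dispersions
(SAD/SDD via the fixed principal point), this implementation reproduces them
closely.

## Problem sizes

The packaged acceptance computation uses 1000 replicates for the 25-image
baseline plan and 300 replicates for the 125- and 225-image plans — the
chi-square CI half-widths are then 1-4% of each SD, comfortably inside the
comparison bands used.
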