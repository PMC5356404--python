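# Methods

`aorta4d` implements a quantitative 4D-flow CMR analysis of thoracic aortic
hemodynamics: velocity-field corrections, PC-MRA-based lumen segmentation,
three-dimensional systolic wall shear stress (WSS) over ten anatomic wall
regions, pathline-based grading of secondary flow patterns, BSA-indexed
aortic morphometry, and the nonparametric group statistics that connect
regional WSS to regional vessel size.  Because in-vivo validation data carry
no ground truth, every quantitative step is validated on synthetic phantoms
whose velocity fields — and therefore whose WSS, rotation and diameters —
are known in closed form.

## The phantom model

The generator imposes velocity fields analytically on two geometries: a
straight tube and a "candy cane" (two straight limbs joined by a half-torus
arch, all centerline points coplanar; that plane is the reference arch plane
used downstream to split the wall into inner/outer halves).  It does not
solve the Navier–Stokes equations; the point is that ground truth is exact
by construction, at desk scale.

* **Axial profile.** Each cross-section carries a parabolic
  (Poiseuille-shaped) axial profile with no-slip at the wall,
  `v(r, s, t) = v_peak · (R_ref/R(s))² · w(t) · (1 − r²/R(s)²)`.
  The `(R_ref/R)²` factor conserves volumetric flow rate where the radius
  profile varies (e.g. a Gaussian bulge emulating a dilated
  proximal-descending segment), so wall shear scales as `R⁻³` at fixed flow —
  the mechanism behind the inverse size–WSS relationship the statistics
  module tests.
* **Ground-truth WSS.** From the imposed wall gradient,
  `τ(s, t) = 2 μ v_center(s) w(t) / R(s)`, exactly.  For the reference tube
  (R = 10 mm, v_peak = 100 cm/s, μ = 3.2 mPa·s) this is 0.64 Pa at peak
  systole.  Blood viscosity defaults to μ = 3.2 mPa·s (the standard
  large-vessel assumption) and is configurable; every WSS value scales
  linearly with it.
* **Waveform.** 20 frames of 40 ms by default; a raised-cosine systolic bump
  over frames 2–8 peaking at frame 5, on a 10 % diastolic baseline.  Spacing
  defaults to (2.4, 1.8, 2.4) mm and venc to 150 cm/s — mid-range values for
  a pediatric thoracic 4D-flow protocol.
* **Helix decoration.** A tangential component `v_θ = k r v_axial` (k in
  rad/mm) makes the rotation per unit advected distance uniform across the
  lumen: every traversing particle accumulates exactly `swirl_deg_per_cm`
  per centimeter, giving an exact rotation truth for helix grading.
* **Vortex pocket.** A solid-body rotation about an axis perpendicular to
  the bulk flow is blended into the field: inside the core radius `a` the
  bulk flow is fully replaced (closed streamlines, retrograde velocity on
  one side), decaying smoothly to the undisturbed field at `2a`.  A particle
  at core distance d < a revolves at exactly ω = 10·v_rim/a rad/s, so the
  revolve angle over any window is exact.  The blend makes the combined
  field slightly compressible inside the transition shell; vortex phantoms
  are therefore used for grading, not for WSS truth.  The vortex phantom
  uses a moderate bulk speed (15 cm/s): a pocket revolving half a turn per
  cycle moves at under 3 cm/s, and a pattern that slow embedded in 100 cm/s
  bulk flow would be physically unresolvable at realistic noise — matching
  the physiology emulated, a separated slow recirculation in a dilated
  descending segment.
* **Degradations.** Gaussian velocity noise of standard deviation
  v_peak/snr per component; a first-order eddy-current-like offset
  `a₀ + aₓx + a_yy + a_zz` (cm/s, physical mm coordinates) added everywhere
  including a 3-voxel static-tissue shell around the lumen; and modular
  wrapping of each component into [−venc, venc).  All randomness flows
  through a single seed; generation is bit-reproducible.

What the phantoms do **not** emulate: oscillatory (Womersley) profiles,
turbulence, wall motion, k-space/MR signal formation, partial-volume
magnitude decay, or anatomic variability.  Tests passing on phantoms
demonstrate the correctness of the numerics under the stated flow model,
not clinical accuracy on patient data.

## Corrections

* **Aliasing.** A wrap is a shift by an exact multiple of 2·venc, so a
  correctly identified wrap is undone exactly.  Two references are used: a
  temporal 3-frame median (aliasing concentrates in the fastest frames,
  whose neighbours are clean even inside a large wrapped core — a purely
  spatial median stalls there, because a compact wrapped region is locally
  self-consistent and the median at its boundary lands mid-jump), then an
  iterated 6-neighborhood spatial median that peels remaining wrapped voxels
  layer by layer (cap 10 iterations; non-convergence raises).  Voxels
  consistent with their reference are untouched; the operation is
  idempotent.
* **Eddy currents.** Per frame and component, a first-order polynomial is
  least-squares fitted to velocities in static tissue and subtracted
  everywhere.  The fit is exact for any first-order offset on noiseless
  data; order 1 is deliberate — higher orders risk absorbing true flow.
* **Noise mask.** Voxels whose time-averaged magnitude falls below 10 % of
  the 99th-percentile magnitude are marked unreliable (masking, not
  filtering).
* **PC-MRA.** Mean over the five systolic frames (peak ± 2) of
  magnitude·‖v‖ — the standard pseudo complex-difference surrogate.  Static
  tissue scores zero regardless of signal magnitude.

## Segmentation and meshing

Segmentation is a seeded dual-threshold (hysteresis) region grow: a strong
vessel core at `threshold_rel` (default 0.2) of the 99th-percentile PC-MRA,
expanded geodesically into the connected support at `low_rel` (default
0.02), then hole-filled.  The expansion is essential, not cosmetic: on an
angiogram whose brightness falls smoothly to zero at the wall (any laminar
profile), a single relative threshold t captures only `r ≤ R√(1−t)` — at
t = 0.2 that bounds the achievable Dice against the true lumen at 0.889.
Detection and extent are therefore separated, as in hysteresis edge
detection.  Raising `threshold_rel` never adds voxels.

The wall mesh is the marching-cubes iso-surface at the 0.5 level of the
σ = 0.5-voxel Gaussian-smoothed mask (smoothing avoids staircase normals),
with inward unit normals from the gradient of the smoothed occupancy and
barycentric (area/3) vertex areas.  Masks touching the volume border are
rejected; flat tube ends are closed by the iso-surface itself, and cap
neighborhoods are excluded from regional WSS by the arc-length limits of
the wall partition.

## Wall shear stress

At each wall vertex, velocity is sampled by trilinear interpolation at
distances 0, h, 2h along the inward normal; the wall sample is forced to
zero (no-slip), a quadratic through the three points is differentiated at
the wall, and the tangential projection scaled by μ gives the WSS vector:
`τ = μ ∂v_t/∂n`.  This is the wall-normal-derivative convention (not the
full viscous stress tensor).  The constrained quadratic is the minimal
deterministic form of the smoothing-spline approach used for in-vivo 3D WSS
and is exact for the phantom's parabolic profile.

Numerical choices.  The sampling step defaults to h = 1.5× the finest voxel
spacing: with h equal to one voxel, the trilinear stencil of the first
off-wall sample straddles zero-filled exterior voxels and biases the
gradient by several percent; 1.5 voxels clears the stencil while the
quadratic remains exact for the parabolic profile.  Wall placement
dominates the error budget: forcing no-slip at a surface displaced by Δ
from the true wall perturbs the fitted gradient by ≈ 3Δ/(2h), so per-vertex
WSS accuracy is validated on the phantom's analytic wall mesh (exact vertex
positions and normals), while segmentation accuracy is scored separately
(Dice, mesh-radius error).  On segmentation-derived meshes, WSS should be
read as resolution-limited — the same caveat that applies to in-vivo 3D
WSS, which is systematically underestimated at clinical voxel sizes.

Systolic WSS magnitude is the mean over the five frames centered on peak
systole of the per-frame vector magnitudes (magnitude-then-average).  Peak
systole is the earliest frame of maximal lumen-mean speed among frames that
admit the ±2 window; a strictly faster boundary frame raises an error.
Regional means are area-weighted (vertex areas, hence mesh-resolution
independent) over ten regions: inner/outer × {pAAo, dAAo, arch, pDAo,
dDAo}, bounded along the centerline by the STJ, midAAo, dAAo, isthmus,
midDAo and dDAo landmarks; the inner/outer split projects each vertex's
offset onto the in-arch-plane direction toward the centerline centroid
(positive = concave = inner).  For a perfectly straight vessel that
direction is degenerate and a fixed in-plane direction is substituted — the
split is then an arbitrary but consistent halving.  Vertices outside the
landmark range (end caps, the root) and vertices inside user-supplied
branch masks are excluded; empty regions are reported as missing, never as
zero.

## Centerline and morphometry

The centerline is the ridge of the interior distance transform, computed as
a graph path: the two geodesically farthest lumen voxels are found by a
double Dijkstra sweep over the 26-connected voxel graph, each endpoint is
snapped to the nearby deepest voxel (maximizing wall distance minus half
the walked distance, so the nearest on-axis voxel wins), and the connecting
path is recomputed with edge costs divided by the squared wall distance,
pinning it to the medial ridge.  A coverage check — every lumen voxel must
lie within twice the maximal wall distance of the path — rejects branching
vessels.  The path is smoothed with a cubic smoothing spline and resampled;
the least-squares plane of the points defines the arch plane.  (A
binary-skeleton route was abandoned: the installed 3D skeletonization
returns an empty skeleton for tubes whose axis falls between voxel
centers.)

Landmarks are supplied as arc-length fractions (anatomic triggers such as
"at the level of the right pulmonary artery" are not computable from a
lumen mask alone).  Diameters are measured in the plane orthogonal to the
local tangent, rasterized at 4× in-plane upsampling, as the maximal caliper
(Feret) diameter of the cross-section component containing the centerline —
the inner-edge to inner-edge convention; for an elliptical section this
reads the major axis.  Body surface area uses Mosteller's formula
√(height·weight/3600).  Z-scores are `(d − mean(BSA))/sd` against a
normative model of the form `mean = a + b√BSA` per landmark; the shipped
default coefficients are synthetic stand-ins shaped like published
pediatric nomograms (clearly flagged in their provenance string), and the
proximal-descending landmark is referenced to the isthmus entry, following
clinical practice when no dedicated pDAo nomogram exists.  A Z-score ≥ 2.0
(boundary inclusive) classifies the level as dilated and drives the
subgrouping into dilated/non-dilated patient groups.

## Flow patterns

Pathlines are advected with classical RK4 through the velocity field
(trilinear in space, linear in time; endpoint error shrinks ≥ 8× when dt is
halved), stopping at lumen exit or cycle end.  Grading uses the clinical
3-point ordinal scale — 0: no pattern; 1: rotation < 360°; 2: rotation
≥ 360° — with a presence threshold of a quarter turn (90°, configurable)
separating grade 0 from grade 1, since the scale itself only defines the
360° split.

* **Helix.** For every pathline traversing the segment, the signed rotation
  of its centerline-offset vector about the local tangent is accumulated;
  the segment rotation is the 90th percentile of the absolute cumulative
  rotations (robust to single outlier trajectories).  At least 20
  traversing pathlines are required.
* **Vortex.** Samples whose velocity deviates > 90° from the local tangent
  (and exceed a speed floor of 15 % of the segment's 95th-percentile sample
  speed, rejecting noise on near-stagnant samples) are pooled; the cluster
  is the neighborhood of their spatial density mode, so reversed samples
  scattered by noise cannot dilute a localized pattern.  The rotation-plane
  normal comes from the SVD of the cluster *velocities* (reversed samples
  cover only the retrograde half of an orbit, so their positions are
  one-sided), and the revolve center from a least-squares solid-body
  rotation fit `v = ωJ(p − c)` — the retrograde-sample centroid is displaced
  from the orbit center and winding about it is near zero.  Per
  contributing pathline, the signed revolve about the core over its
  contiguous passage is accumulated; the statistic is again the 90th
  percentile.  Because a trapped particle never traverses the segment, the
  precondition is 20 pathlines *visiting* it.
* **Seeding.** The default emitter is an inlet plane of 200 uniform seeds
  released every frame (the standard pathline-movie protocol), which is
  what helix grading uses.  Vortex grading additionally seeds the lumen
  volume: the pocket's blended core deflects incoming particles around
  itself, so inlet-only seeding cannot populate a localized recirculation —
  whereas a real pathline movie, integrated over the cycle, does fill it.

## Statistics

Mann-Whitney U (pair counting with half-ties), Kruskal-Wallis H with tie
correction, Pearson r with the t reference, the 2×2 Pearson chi-square
without continuity correction, and Cohen's κ with the conventional
agreement bands are implemented directly so their small-sample behaviour is
fully specified.  The Mann-Whitney p-value is exact — enumeration over all
C(n₁+n₂, n₁) group assignments — for combined n ≤ 12, and a tie-corrected
normal approximation (no continuity correction) above; the switch is
logged in the report.  All tests are two-sided.  No multiple-testing
correction is applied by default, with Holm adjustment available behind a
flag.  The synthetic cohort generator draws per-group landmark Z-scores,
derives diameters through the normative model, and generates the
proximal-descending WSS from the fixed-flow-rate scaling
`τ = τ_ref (d_ref/d)³` with lognormal noise — so the inverse diameter–WSS
correlation the report computes has a known sign and approximate magnitude
at the study's sample sizes (25 + 21).

## Problem sizes

Validation runs use deliberately desk-scale phantoms: the reference WSS
tube at 1 mm isotropic (≈ 10⁵ lumen voxels), the convergence sweep at
2.0/1.0/0.5 mm on a 60 mm tube with a 7-frame cycle, the candy cane at
≈ 2 mm anisotropic spacing, and 200–400 pathline seeds per grading run.
The full test suite and the acceptance script each complete in well under a
minute on one CPU.

## Known limitations

* WSS truth and estimator are defined for the wall-normal-derivative
  convention; the full-deformation-tensor WSS differs on strongly curved or
  secondary-flow walls.
* The inner/outer split is a geometric surrogate for regions that are drawn
  manually on patient data; near the limb ends of a straight vessel the
  concave direction is ill-defined.
* Vortex grading assumes a single dominant recirculation per segment (one
  density mode); co-existing counter-rotating pockets would be summarized
  by the stronger one.
* The unwrapping temporal reference assumes aliasing is confined to a
  minority of frames per voxel; velocities aliased in every frame (venc far
  below peak speed everywhere) are not recoverable by this scheme.
* The normative default coefficients are synthetic; Z-scores computed with
  them are for pipeline exercise, not clinical interpretation.
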