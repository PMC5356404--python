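# aorta4d

Quantitative analysis of thoracic aortic hemodynamics from 4D-flow CMR —
time-resolved phase-contrast MRI encoding all three velocity components over
a 3D volume across the cardiac cycle.  The package is aimed at
cardiovascular imaging researchers studying aortopathy (e.g.
connective-tissue disease with root and proximal-descending dilatation),
where regional wall shear stress and secondary flow patterns are candidate
markers of disease severity beyond diameter alone.

The pipeline covers:

* **corrections** — velocity anti-aliasing (temporal + spatial median
  unwrapping), first-order eddy-current offset removal fitted on static
  tissue, low-signal masking, and the PC-MRA angiogram;
* **segmentation** — seeded hysteresis region grow on the PC-MRA, wall
  meshing with inward normals;
* **wall shear stress** — per-vertex 3D WSS vectors from the wall-normal
  velocity gradient, τ = μ ∂v_t/∂n with no-slip enforced, averaged over the
  five frames centered on peak systole and summarized over ten anatomic
  wall regions (inner/outer × pAAo, dAAo, arch, pDAo, dDAo) with branch and
  cap exclusion;
* **morphometry** — distance-transform-ridge centerline, maximal-caliper
  (inner-edge to inner-edge) landmark diameters, percent segment size
  change |d_prox − d_dist|/d_prox × 100, Mosteller BSA √(h·w/3600), and
  BSA-indexed aortic Z-scores with the z ≥ 2.0 dilatation rule;
* **flow patterns** — RK4 pathlines and quantitative helix/vortex grading
  on the clinical 3-point scale (0: none, 1: rotation < 360°, 2: ≥ 360°);
* **statistics** — exact small-sample Mann-Whitney, Kruskal-Wallis,
  Pearson correlation, 2×2 chi-square and Cohen's κ, assembled into a
  cohort comparison report.

Because patient acquisitions carry no ground truth, everything is validated
on synthetic phantoms (straight tubes and a candy-cane aorta) whose imposed
parabolic flow makes WSS, rotation and diameters exact in closed form: for
a tube of radius R with centerline speed v, τ_w = 2 μ v / R, and at fixed
flow rate τ_w ∝ R⁻³ — the mechanism behind the inverse relationship between
vessel size and regional WSS that the statistics module tests.  See
`docs/methods.md` for the model and its limitations.

## Worked example

```python
import numpy as np
import aorta4d as a
from aorta4d import geometry, preprocess, segmentation, wss

# a clean tube phantom: R = 10 mm, v_peak = 100 cm/s, 1 mm voxels
spec = a.PhantomSpec(geometry_kind="straight_tube", radius_mm=10.0,
                     length_mm=100.0, spacing_mm=(1.0, 1.0, 1.0),
                     v_peak_cm_s=100.0)
field, truth = a.make_phantom(spec)

# WSS on the analytic wall mesh
mesh = a.make_true_wall_mesh(truth, ds_mm=2.0, n_theta=48)
wmap = wss.systolic_mean_wss(field, mesh, truth.true_mask)
print(f"peak frame:          {wmap.peak_frame_index}")
print(f"analytic peak WSS:   {truth.true_wss_peak_pa[0]:.3f} Pa")
print(f"median vertex WSS:   {np.median(np.linalg.norm(wmap.vectors_pa[2], axis=1)):.3f} Pa")

# segmentation from the PC-MRA, then a landmark diameter and Z-score
pcmra = preprocess.compute_pcmra(field)
seed = np.unravel_index(np.argmax(pcmra), pcmra.shape)
mask = segmentation.segment_lumen(pcmra, field.spacing_mm, seed,
                                  origin_mm=field.origin_mm)
print(f"segmentation Dice:   {segmentation.dice(mask.volume, truth.true_mask):.3f}")

cl = geometry.centerline_from_points(truth.true_centerline_points_mm,
                                     landmarks={"pDAo": 0.5})
d = geometry.measure_diameter(mask, cl, "pDAo")
rec = geometry.aortic_zscore(d, geometry.bsa_mosteller(170.0, 60.0), "pDAo",
                             geometry.default_normative_model())
print(f"diameter at landmark: {d:.1f} mm  (true 20.0 mm)")
print(f"Z-score:             {rec.z_score:+.2f}  dilated: {rec.dilated}")
```

prints

```
peak frame:          5
analytic peak WSS:   0.640 Pa
median vertex WSS:   0.630 Pa
segmentation Dice:   1.000
diameter at landmark: 20.6 mm  (true 20.0 mm)
Z-score:             -0.74  dilated: False
```

The recovered wall shear stress sits within 2 % of the analytic 0.64 Pa at
this resolution; the segmented lumen matches the true mask; the measured
diameter is within one voxel of truth; and against the (synthetic) pediatric
normative model a 20 mm descending aorta at BSA 1.68 m² is comfortably
non-dilated.

A command-line interface mirrors the library
(`aorta4d simulate | preprocess | segment | geometry | wss | patterns |
report`); run `aorta4d --help` for the options.

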