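# tortuflow

Quantitative tortuosity and blood-flow metrics for the main brain-feeding
neck arteries — the internal carotid (ICA) and vertebral (VA) arteries —
from MR angiography, with a synthetic-phantom module that makes every
stage testable against analytic ground truth.

Extracranial arteries grow measurably more tortuous with age, and those
geometric changes accompany reduced blood flow; grading them objectively
requires reproducible numbers rather than visual impressions.
`tortuflow` implements the full measurement chain for the two routine
acquisitions involved:

* **3-D TOF-MRA** (bright blood): artery segmentation inside an ROI Ω by
  the intensity-statistics rule *I(x) > μ + j·σ* with automatic downward
  search of *j* over 6 → 4; 18-connectivity component linking; centerline
  extraction by solving the Eikonal equation |∇T|·F = 1 with a
  multi-stencils fast-marching scheme on a distance-transform medialness
  speed, followed by gradient-descent backtracing.
* **Tortuosity metrics** from the centerline:
  TI = AL/DL (arc over chord length), BL = max perpendicular distance to
  the endpoint line (mm), and ICM = N·TI where N is an automated count of
  turning points (persistent flips of the Frenet binormal).
* **2-D PC-MRI** (velocity-encoded): vessel mask at 5× the background
  magnitude noise, velocity v = VENC·φ/π, blood flux (ml/min), maximum
  velocity MaxV (cm/s), and unit-mass CBF = Σ(four-artery flux)/brain
  mass × 100 (ml/min/100 g); scan–rescan coefficient of variation
  |m₁−m₂|/(√2·mean).
* **Phantoms**: parametric tubes (straight / semicircle / sinusoid /
  helix / composite) rasterised with TOF-like contrast and known
  AL, DL, TI, BL, N; Poiseuille flow phantoms with closed-form flux; a
  seeded synthetic ageing cohort whose geometry steepens and peak
  velocity declines with age.

See `docs/methods.md` for the model details, parameter defaults and
numerical choices.

## Worked example

Generate a helical vessel phantom (radius 10 mm, pitch 20 mm, two
turns), run the pipeline, and compare with the closed-form arc length
2·√((2π·10)² + 20²) ≈ 131.88 mm:

```python
import tortuflow as tf
from tortuflow.pipeline import suggest_roi

spec = tf.TubePhantomSpec(
    curve=tf.CurveSpec("helix", {"radius": 10.0, "pitch": 20.0, "n_turns": 2}),
    tube_radius=2.0, voxel_spacing=(1.0, 1.0, 1.0), seed=3)
phantom = tf.rasterize_tube(spec)

j_star, mask = tf.select_j(phantom.volume, suggest_roi(phantom))
centerline = tf.extract_centerline(
    mask,
    source=tf.nearest_mask_voxel(mask, phantom.truth.points[0]),
    target=tf.nearest_mask_voxel(mask, phantom.truth.points[-1]))
result = tf.summarize(centerline)
print(f"j* = {j_star}")
print(f"AL = {result.al:.1f} mm (truth {phantom.truth.al_true:.1f} mm)")
print(f"TI = {result.ti:.2f}, BL = {result.bl:.1f} mm, N = {result.n}, ICM = {result.icm:.2f}")
```

Output:

```
j* = 6.0
AL = 130.2 mm (truth 131.9 mm)
TI = 3.25, BL = 19.8 mm, N = 0, ICM = 0.00
```

The segmentation is accepted at the top of the j range (the phantom's
contrast is 10× the noise), the recovered arc length is within 1.3 % of
the analytic value, TI ≈ AL/DL = 131.9/40, BL ≈ the helix diameter (the
farthest point from the vertical endpoint chord), and a helix has no
curvature-sign changes, so N = 0 and ICM = 0.

For flow, a Poiseuille phantom (R = 10 px at 0.45 mm, v_max = 40 cm/s,
VENC = 80 cm/s) recovers its continuous-profile flux
(π R² /100)·(v_max/2)·60 ≈ 763 ml/min to within a fraction of a percent:

```python
pair, truth = tf.make_pc_phantom(tf.FlowPhantomSpec(seed=5))
flow = tf.quantify_flow(pair)
print(f"flux = {flow.flux:.0f} ml/min (truth {truth.flux_true:.0f}), MaxV = {flow.max_velocity:.1f} cm/s")
# flux = 762 ml/min (truth 763), MaxV = 40.0 cm/s
```

A command-line interface mirrors the library
(`tortuflow phantom | segment | centerline | tortuosity | flow | cbf |
cohort-gen | run-cohort | trend`); see `tortuflow --help`.

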