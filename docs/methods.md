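# Methods

`tortuflow` quantifies the geometry (tortuosity) and hemodynamics (flux,
peak velocity, unit-mass CBF) of the four main brain-feeding neck
arteries — left/right internal carotid (ICA) and vertebral (VA) — from
two routine MR angiography acquisitions: a 3-D time-of-flight (TOF)
angiogram in which inflowing blood is bright against saturated tissue,
and a 2-D phase-contrast (PC) slice in which through-plane velocity is
encoded linearly in the voxel phase up to the VENC limit.  Because no
imaging data accompany the method, every stage is validated on synthetic
tubular phantoms with analytic ground truth.

## Segmentation

Within an operator-drawn ROI Ω that contains the artery *and* its
surrounding tissue, artery voxels are those with

    I(x) > μ + j·σ,

where μ, σ are the mean and population standard deviation of Ω.  Since
arterial signal is inhomogeneous across subjects, j is searched downward
from `j_max = 6` to `j_min = 4` in steps of 0.25; the first j whose
largest 18-connected component (voxels joined by faces or edges, not
corners) spans the full slice extent of the ROI is accepted.
Slab-spanning continuity is the computable surrogate for "high enough to
exclude tissue, low enough to keep the artery intact": a neck artery
crosses the whole axial slab, disconnected tissue islands do not.  If no
j in range produces a spanning component the segmentation fails loudly —
this is the per-artery failure mode the pipeline tallies.

Two consequences of defining σ over the whole ROI (artery included) are
worth knowing:

* **Detectability floor.** Because the threshold can never drop below
  μ + 4σ, a vessel whose contrast is near 5·σ_noise is only partially
  captured (the cutoff sits within one noise standard deviation of the
  lumen intensity).  Reliable segmentation (Dice ≥ 0.9) needs contrast
  around 7·σ_noise or more; the phantom default (SNR ≈ 10) sits safely
  above this floor.
* **ROI size matters.** The artery's own bright voxels inflate σ.  The
  rule behaves well when the artery occupies ≲ 1 % of the ROI, which a
  typical neck FOV satisfies; the phantom generator therefore surrounds
  its tubes with ~25 mm of in-plane "tissue" by default.

An Otsu threshold is available as an alternative mode
(`otsu_threshold`); note Otsu assumes comparably sized classes and needs
a tight ROI around the vessel.

j step of 0.25 makes the acceptance criterion, not the search grid,
determine j*.  σ = 0 (no contrast) is treated as a misconfiguration
error rather than an all-true mask.

## Centerline extraction

The segmented component is first cleaned of fully enclosed interior
holes (threshold noise occasionally removes single lumen voxels; a hole
on the medial axis would force the path to detour around it).  A
medialness speed map is built from the anisotropic Euclidean distance
transform,

    F(x) = (EDT(x) / max EDT)^γ,  γ = 2,

so that the front travels fastest along the vessel's medial axis.  The
Eikonal equation |∇T|·F = 1 is solved by fast marching over multiple
stencils: the axis-aligned stencil always, plus an in-plane diagonal
stencil for every coordinate plane with equal spacing (diagonal
directions are orthogonal in physical space only then — with the
1.0 × 1.0 × 1.5 mm TOF voxel, the xy-diagonals qualify).  Second-order
upwind differences are used wherever two accepted upwind values are
available, and the 2-voxel ball around the source is initialised with
local analytic distances, removing the point-source error that dominates
first-order schemes.  On a 21³ uniform-speed grid the arrival error
against the exact Euclidean distance stays well under one voxel.

The centerline is recovered by descending the arrival-time gradient from
the target to the source: midpoint (second-order) integration with a
step of 0.4 × min spacing, trilinearly interpolated gradients, and a
small step *towards* the lowest-arrival neighbour wherever the
interpolated gradient stagnates.  The raw path is smoothed with a light
moving average (two voxels of arc) to remove sub-voxel descent jitter —
shortening of real geometry is O(w²/R²), under 0.1 % at vessel-scale
curvature radii — and resampled to a uniform 1 mm arc-length step.

Endpoints default to the centroids of the lowest and highest occupied
slices, the natural convention for neck arteries running head–foot
through the slab.  For geometries whose end tangents are transverse
(e.g. a semicircular arc), callers pass explicit endpoints; the phantom
tests snap them from the known curve ends.  A mask occupying a single
slice is rejected as "complicated geometry" — the loop-back failure mode
that also defeats threshold-based tracking on real coiled arteries.

## Tortuosity metrics

All metrics are computed from the same resampled (1 mm) and
moving-average-smoothed (5 mm window, endpoints pinned) curve:

* **AL** — arc length, the sum of consecutive point distances;
* **DL** — chord length between the endpoints;
* **TI** = AL / DL ≥ 1 (1 for a straight vessel);
* **BL** — maximum perpendicular distance from the path to the infinite
  line through its endpoints ("extent of curving", mm).  A config switch
  selects the chord *segment* instead of the infinite line; for
  vessel-like curves the maximum falls over the chord either way;
* **N** — number of turning points (below);
* **ICM** = N × TI, computed exactly as that product.

Endpoint pinning in the smoother matters: an unconstrained moving
average contracts the curve ends, biasing DL low and TI high by several
percent on strongly curved arcs.

### Turning-point detection

Operator counting of turning points cannot be reproduced by software, so
N is automated.  Discrete Frenet frames are computed from a
moving-average-smoothed curvature-vector field (residual extraction
jitter has near-random direction and cancels in the window mean), gated
at κ_min = 0.01 mm⁻¹.  The counted quantity is the **binormal**
b = t × n: along a planar arc of fixed curvature sign the binormal is
constant regardless of how much the tangent turns, it flips by 180° at
an inflection, and torsion only drifts it slowly.  A candidate binormal
direction must persist (as an exponential moving average that follows
torsion drift) for one smoothing window of arc length before it is
confirmed; a jump between successive confirmed directions with squared
distance above 1.0 (> 60° of rotation) is counted as a turning point,
with counted points at least 5 mm apart and the first/last window of the
curve excluded (inflections are interior; tracked ends carry seed
artefacts).

A simpler rule — thresholding jumps between successive Frenet *normals* —
is exact on noise-free curves but over-counts severely on extracted
centerlines, because the normal rotates with the tangent between
inflections and is jitter-dominated wherever true curvature is small.
The persistent-binormal rule reproduces the analytic interior
curvature-sign-change count exactly on straight lines, semicircles,
helices and 1–3-period sinusoids, both analytic and pipeline-extracted,
across noise seeds.

## Flow quantification

Phase maps to velocity as v = VENC·φ/π (radians; scanner integer
scalings must be converted upstream).  The vessel mask keeps ROI pixels
whose magnitude exceeds 5 × the mean magnitude of a background noise
region (user box or the four image corners by default; the mean is used
because a "5 ×" multiple of it lands thresholds at bright-lumen levels).
Flux is the absolute value of the signed velocity sum over the mask
times pixel area, in ml/min — single-slice, non-gated, unidirectional
through-plane flow.  MaxV is the largest |v| in the mask.  Unit-mass CBF
sums the four arteries' fluxes and normalises by brain parenchyma mass
(grams directly, or parenchymal volume × 1.06 g/ml).  No eddy-current
phase-offset correction is applied by default (an optional offset
subtraction exists but is disabled).

Scan–rescan reproducibility uses the two-measurement within-subject
coefficient of variation CoV = |m₁ − m₂| / (√2 · mean(m₁, m₂)); a config
flag selects a plain 2·mean denominator.

## Synthetic phantoms

**Tube phantoms.** Parametric curves (straight, semicircle, sinusoid,
helix, two-harmonic composite) run along the slice axis by default.
Ground truth: AL analytic where closed forms exist, else adaptive
quadrature at 1e-10 relative tolerance; DL from the endpoints; BL as the
dense-sample point-to-chord-line maximum (exactly R for the semicircle);
N as the analytic count of interior curvature-sign changes (2k − 1 for k
full sinusoid periods).  The tube of constant radius is rasterised by
distance to dense curve samples (threshold widened by the sampling slack
√(r² + (δ/2)²) so boundary voxels are kept) and cut flush at the curve
endpoints by local planes perpendicular to the end tangents — an artery
truncated by the imaging slab, not a capped rod; spherical caps would
extend the tracked path and bias TI low.  Contrast defaults emulate TOF:
lumen 200, tissue 100, Gaussian noise sd 10 (SNR ≈ 10 — the scans report
no noise figures, so this is a free, realistic choice), voxels
1.0 × 1.0 × 1.5 mm, ~25 mm in-plane tissue margin.  Not modelled: bias
fields, flow-related signal loss, saturation effects, bifurcations —
passing tests show the geometry pipeline is correct, not that it is
robust to every MR artefact.

**Scan–rescan pairs** differ only in noise realisation and a random
sub-voxel rigid translation (≤ 0.5 voxel per axis), the dominant
inter-session effects at neck-FOV scale.

**Flow phantoms.** A circular vessel of radius R pixels carries a
laminar Poiseuille profile v(r) = v_max(1 − r²/R²); phase = π·v/VENC
(wrap-free by construction, v_max ≤ VENC), magnitude is two-level with
Gaussian noise.  True flux is the continuous-profile integral
(π R² / 100) · (v_max/2) · 60 ml/min.

**Ageing cohort.** `make_cohort` draws ages uniformly on 20–88 years and
links geometry and flow to age linearly with Gaussian between-subject
scatter: sinusoid amplitude 7 mm + 0.13 mm/yr (sd 1.2) on a 30 mm
wavelength, two periods — spanning measured TI ≈ 1.3–2.8, the reported
ICA range — and v_max 36 cm/s − 0.18 cm/s/yr (sd 3.5), matching the
reported decade trend of ICA peak velocity.  The generator is
deterministic under its seed; the pipeline itself has no randomness.

## Numerical choices and degenerate inputs

* Population (not sample) standard deviation for Ω, matching the
  threshold definition.
* Causality enforcement in the Eikonal update: directions whose upwind
  value exceeds the candidate solution are dropped, largest first.
* Backtrace stagnation raises a convergence error after 10× the
  reachable-voxel count of steps.
* Coincident centerline endpoints (closed loops) make DL, TI and BL
  undefined and are rejected.
* TI is clamped at 1 from below to absorb eps-level AL < DL on perfectly
  straight resampled lines.
* Problem sizes used in tests and the acceptance script (100 mm tubes at
  1 mm voxels, 21³ Eikonal grids, 7 rescan pairs, 100-subject cohorts)
  were chosen so each stage's error is dominated by method, not
  statistics, while a full run stays in the minutes range on one CPU.

## Known limitations

* The μ + j·σ rule cannot segment vessels with contrast below ~5–7 noise
  standard deviations or ROIs where the artery is a large area fraction
  (σ inflation); both are documented behaviours, not bugs.
* Single-path tracking only: bifurcating trees and self-overlapping
  coils are out of scope (the cervical ICA/VA segments are branch-free).
* Turning-point counting assumes a mostly planar-by-parts vessel course;
  genuinely high-torsion curves have no well-defined inflection count.
* Phase wrap (v > VENC) and cardiac-gated waveforms are not handled.
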