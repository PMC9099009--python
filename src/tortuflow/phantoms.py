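"""Synthetic tubular phantoms with analytic ground truth.

No imaging data accompany the method, so every pipeline stage is
validated on phantoms that emulate the two acquisitions:

* bright tubular "arteries" on a darker tissue background with additive
  Gaussian noise, rasterised on an (optionally anisotropic) voxel grid
  from parametric 3-D curves whose arc length, chord length, bending
  length and inflection count are known in closed form (or by adaptive
  quadrature converged to 1e-8);
* phase/magnitude image pairs with a circular vessel carrying laminar
  (Poiseuille) through-plane flow encoded linearly in the phase up to
  VENC; phase wrap is deliberately not modelled (v_max <= VENC).

Curve families run along the slice (z) axis by default, like neck
arteries through an axial slab.  Defaults emulate the study conditions:
voxel 1.0 x 1.0 x 1.5 mm, SNR about 10 (foreground-background contrast
= 10 x noise sd), PC pixels 0.45 mm, VENC 80 cm/s; the sinusoid
amplitudes used by the cohort generator are chosen so the true TI spans
the internal-carotid range (roughly 1.4 - 2.8).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import integrate
from scipy.spatial import cKDTree

from .errors import PhantomSpecError
from .image_io import Volume3D
from .segmentation import VesselMask
from .flow import PhaseMagPair

CURVE_FAMILIES = ("straight", "semicircle", "sinusoid", "helix", "composite")
_AXES = {"x": (2, 1, 0), "y": (0, 2, 1), "z": (0, 1, 2)}


# ---------------------------------------------------------------------------
# curve specifications and analytic truths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveSpec:
    """Parametric 3-D vessel course.

    params by family (all lengths in mm):
      straight   length
      semicircle radius
      sinusoid   amplitude, wavelength, n_periods
      helix      radius, pitch, n_turns
      composite  amplitude, wavelength, n_periods, amplitude2, wavelength2
    """

    family: str
    params: dict
    axis: str = "z"

    def __post_init__(self):
        if self.family not in CURVE_FAMILIES:
            raise PhantomSpecError(f"unknown curve family {self.family!r}")
        if self.axis not in _AXES:
            raise PhantomSpecError(f"axis must be one of x/y/z, got {self.axis!r}")
        for key, value in self.params.items():
            if key.startswith(("amplitude", "wavelength", "length", "radius", "pitch")) and value <= 0:
                raise PhantomSpecError(f"{self.family}: parameter {key} must be > 0, got {value}")
        n = self.params.get("n_periods", self.params.get("n_turns"))
        if n is not None and n < 0.5:
            raise PhantomSpecError(f"n_periods/n_turns must be >= 0.5, got {n}")


@dataclass(frozen=True)
class CurveTruth:
    """Densely sampled curve plus its analytic tortuosity ground truth."""

    points: np.ndarray
    al_true: float
    dl_true: float
    ti_true: float
    bl_true: float
    n_true: int

    def __post_init__(self):
        if not (self.al_true >= self.dl_true > 0):
            raise PhantomSpecError("curve truth must satisfy AL >= DL > 0")
        if self.ti_true < 1 or self.bl_true < 0 or self.n_true < 0:
            raise PhantomSpecError("curve truth invariants violated")

    def translated(self, offset) -> "CurveTruth":
        return CurveTruth(self.points + np.asarray(offset, dtype=float),
                          self.al_true, self.dl_true, self.ti_true,
                          self.bl_true, self.n_true)

    def to_json(self) -> str:
        d = {k: (int(v) if k == "n_true" else float(v))
             for k, v in asdict(self).items() if k != "points"}
        return json.dumps(d, indent=2)


def _curve_functions(spec: CurveSpec):
    """Return (position x(z-like param t in [0,1]), dx/dt, d2x_planar/dt2, t_end).

    All families are parameterised on t in [0, 1]; planar families report
    the analytic in-plane second derivative for inflection counting.
    """
    p = spec.params
    fam = spec.family
    if fam == "straight":
        L = p["length"]

        def pos(t):
            return np.column_stack([np.zeros_like(t), np.zeros_like(t), L * t])

        def d1(t):
            return np.column_stack([np.zeros_like(t), np.zeros_like(t), np.full_like(t, L)])

        return pos, d1, None

    if fam == "semicircle":
        R = p["radius"]

        def pos(t):
            th = math.pi * t
            return np.column_stack([R * np.sin(th), np.zeros_like(t), R * (1 - np.cos(th))])

        def d1(t):
            th = math.pi * t
            return math.pi * np.column_stack([R * np.cos(th), np.zeros_like(t), R * np.sin(th)])

        return pos, d1, None

    if fam == "helix":
        r, pitch, n = p["radius"], p["pitch"], p["n_turns"]
        t_end = 2 * math.pi * n

        def pos(t):
            u = t_end * t
            return np.column_stack([r * (np.cos(u) - 1), r * np.sin(u), pitch * u / (2 * math.pi)])

        def d1(t):
            u = t_end * t
            return t_end * np.column_stack([-r * np.sin(u), r * np.cos(u),
                                            np.full_like(u, pitch / (2 * math.pi))])

        return pos, d1, None

    # planar sinusoid / composite: x = f(z), z = L * t
    if fam == "sinusoid":
        A, lam, n = p["amplitude"], p["wavelength"], p["n_periods"]
        L = lam * n
        k = 2 * math.pi / lam

        def f(z):
            return A * np.sin(k * z)

        def fp(z):
            return A * k * np.cos(k * z)

        def fpp(z):
            return -A * k * k * np.sin(k * z)

    else:  # composite: superposition of two sinusoids
        A1, lam1, n = p["amplitude"], p["wavelength"], p["n_periods"]
        A2, lam2 = p["amplitude2"], p["wavelength2"]
        L = lam1 * n
        k1, k2 = 2 * math.pi / lam1, 2 * math.pi / lam2

        def f(z):
            return A1 * np.sin(k1 * z) + A2 * np.sin(k2 * z)

        def fp(z):
            return A1 * k1 * np.cos(k1 * z) + A2 * k2 * np.cos(k2 * z)

        def fpp(z):
            return -A1 * k1 * k1 * np.sin(k1 * z) - A2 * k2 * k2 * np.sin(k2 * z)

    def pos(t):
        z = L * t
        return np.column_stack([f(z), np.zeros_like(t), z])

    def d1(t):
        z = L * t
        return L * np.column_stack([fp(z), np.zeros_like(t), np.ones_like(z)])

    def planar_d2(t):
        return fpp(L * t)

    return pos, d1, planar_d2


def _analytic_arc_length(spec: CurveSpec, d1) -> float:
    p = spec.params
    if spec.family == "straight":
        return p["length"]
    if spec.family == "semicircle":
        return math.pi * p["radius"]
    if spec.family == "helix":
        return p["n_turns"] * math.hypot(2 * math.pi * p["radius"], p["pitch"])
    val, _ = integrate.quad(lambda t: float(np.linalg.norm(d1(np.array([t]))[0])),
                            0.0, 1.0, epsrel=1e-10, limit=400)
    return val


def _analytic_turning_points(spec: CurveSpec, planar_d2) -> int:
    """Interior curvature-sign changes; 0 for constant-sign families."""
    if spec.family in ("straight", "semicircle", "helix"):
        return 0
    if spec.family == "sinusoid":
        two_n = 2 * spec.params["n_periods"]
        if abs(two_n - round(two_n)) < 1e-12:
            return max(int(round(two_n)) - 1, 0)
        return int(math.floor(two_n))
    # composite: count strict sign changes of the analytic second derivative
    t = np.linspace(0, 1, 20001)[1:-1]
    vals = planar_d2(t)
    signs = np.sign(vals)
    signs = signs[signs != 0]
    return int(np.sum(signs[1:] * signs[:-1] < 0))


def _max_line_distance(points: np.ndarray) -> float:
    a, b = points[0], points[-1]
    u = b - a
    u = u / np.linalg.norm(u)
    rel = points - a
    perp = rel - (rel @ u)[:, None] * u[None, :]
    return float(np.linalg.norm(perp, axis=1).max())


def make_curve(spec: CurveSpec, n_points: int = 400) -> CurveTruth:
    """Densely sampled curve with closed-form ground truth.

    AL is analytic where available, else by adaptive quadrature; BL is the
    point-to-chord-line maximum evaluated on a dense (20001-point) sample.
    """
    if n_points < 50:
        raise PhantomSpecError(f"n_points must be >= 50, got {n_points}")
    pos, d1, planar_d2 = _curve_functions(spec)

    t_dense = np.linspace(0.0, 1.0, 20001)
    dense = pos(t_dense)
    al = _analytic_arc_length(spec, d1)
    dl = float(np.linalg.norm(dense[-1] - dense[0]))
    if dl <= 0:
        raise PhantomSpecError(f"{spec.family}: degenerate curve with coincident endpoints")
    bl = 0.0 if spec.family == "straight" else _max_line_distance(dense)
    if spec.family == "semicircle":
        bl = spec.params["radius"]  # exact apex-to-chord distance
    n_true = _analytic_turning_points(spec, planar_d2)

    pts = pos(np.linspace(0.0, 1.0, n_points))
    perm = _AXES[spec.axis]
    pts = pts[:, perm]
    return CurveTruth(points=pts, al_true=al, dl_true=dl, ti_true=al / dl,
                      bl_true=bl, n_true=n_true)


# ---------------------------------------------------------------------------
# TOF-like tube phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TubePhantomSpec:
    """A tube of constant radius around a parametric curve, rasterised with
    TOF-like contrast: bright lumen, darker tissue, Gaussian noise."""

    curve: CurveSpec
    tube_radius: float = 2.0
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.5)
    grid_dims: tuple[int, int, int] | None = None
    fg_intensity: float = 200.0
    bg_mean: float = 100.0
    noise_sd: float = 10.0
    margin_xy: float = 25.0  # in-plane tissue margin: ROI encloses artery + tissue
    seed: int = 0

    def __post_init__(self):
        if self.tube_radius < max(self.voxel_spacing):
            raise PhantomSpecError(
                f"tube radius {self.tube_radius} must be >= max voxel spacing "
                f"{max(self.voxel_spacing)}")
        if self.fg_intensity <= self.bg_mean:
            raise PhantomSpecError("fg_intensity must exceed bg_mean")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be >= 0")


@dataclass(frozen=True)
class TubePhantom:
    """Rasterised phantom: noisy volume, noise-free true mask, placed truth."""

    volume: Volume3D
    true_mask: VesselMask
    truth: CurveTruth
    spec: TubePhantomSpec


def _place_curve(spec: TubePhantomSpec, offset_mm=None):
    """Sample the curve densely and translate it into grid coordinates."""
    truth = make_curve(spec.curve, n_points=500)
    al = truth.al_true
    n_dense = max(500, int(al / 0.1))
    dense = make_curve(spec.curve, n_points=min(n_dense, 20000)).points

    r = spec.tube_radius
    sp = np.asarray(spec.voxel_spacing)
    lo = dense.min(axis=0)
    hi = dense.max(axis=0)
    margin = np.array([max(spec.margin_xy, 2 * r), max(spec.margin_xy, 2 * r), 2 * r])
    shift = margin - lo
    if offset_mm is not None:
        shift = shift + np.asarray(offset_mm, dtype=float)
    dense = dense + shift
    truth = truth.translated(shift)

    if spec.grid_dims is None:
        dims = tuple(int(math.ceil((hi[a] - lo[a] + 2 * margin[a]) / sp[a])) + 1 for a in range(3))
    else:
        dims = tuple(int(d) for d in spec.grid_dims)
    grid_hi = (np.asarray(dims) - 1) * sp
    if (dense.min(axis=0) < r).any() or (dense.max(axis=0) > grid_hi - r).any():
        raise PhantomSpecError(
            f"curve (+ tube radius {r} mm) exits the {dims} grid; "
            "enlarge grid_dims or reduce the curve extent")
    return dense, truth, dims


def rasterize_tube(spec: TubePhantomSpec, _offset_mm=None) -> TubePhantom:
    """Voxels within tube_radius (physical distance to the curve) take
    fg_intensity, others bg_mean; seeded Gaussian noise is added.  The
    noise-free true mask is returned alongside.

    The tube is cut flush at the curve endpoints by planes perpendicular
    to the end tangents, like an artery truncated by the imaging slab,
    rather than closed with spherical caps.
    """
    dense, truth, dims = _place_curve(spec, offset_mm=_offset_mm)
    sp = np.asarray(spec.voxel_spacing)

    ii, jj, kk = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    centers = np.column_stack([ii.ravel() * sp[0], jj.ravel() * sp[1], kk.ravel() * sp[2]])
    tree = cKDTree(dense)
    dist, nearest = tree.query(centers, k=1, workers=-1)
    # distance is measured to discrete curve samples: a point at exact
    # perpendicular distance r sits sqrt(r^2 + (delta/2)^2) from the nearest
    # sample, so widen the threshold by that sampling slack
    delta = np.linalg.norm(np.diff(dense, axis=0), axis=1).max()
    cutoff = math.sqrt(spec.tube_radius ** 2 + (delta / 2.0) ** 2)
    inside = dist <= cutoff + 1e-9
    # flush cuts: drop cap voxels (nearest curve sample is an endpoint)
    # lying beyond the plane through that endpoint perpendicular to the
    # end tangent; the cut is local so it cannot slice distant turns
    n_dense = len(dense)
    for end_idx, other in ((0, 1), (n_dense - 1, n_dense - 2)):
        end = dense[end_idx]
        u = dense[end_idx] - dense[other]
        u = u / np.linalg.norm(u)
        in_cap = nearest == end_idx
        inside &= ~(in_cap & ((centers - end) @ u > 1e-9))
    mask = inside.reshape(dims)

    rng = np.random.default_rng(spec.seed)
    data = np.where(mask, spec.fg_intensity, spec.bg_mean).astype(float)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=dims)
    volume = Volume3D(data, tuple(sp))
    return TubePhantom(volume=volume, true_mask=VesselMask(mask, tuple(sp)),
                       truth=truth, spec=spec)


def make_scan_rescan(spec: TubePhantomSpec, seed_pair: tuple[int, int],
                     shift_mm=None) -> tuple[TubePhantom, TubePhantom]:
    """Two phantoms of the same vessel differing only in the noise
    realisation and a random sub-voxel repositioning translation."""
    s1, s2 = (int(s) for s in seed_pair)
    import dataclasses as _dc
    if shift_mm is None:
        rng = np.random.default_rng((s1, s2, 0x5e55))
        shift_mm = rng.uniform(-0.5, 0.5, size=3) * np.asarray(spec.voxel_spacing)
    shift_mm = np.asarray(shift_mm, dtype=float)
    if (np.abs(shift_mm) > np.asarray(spec.voxel_spacing) + 1e-12).any():
        raise PhantomSpecError(f"repositioning shift {shift_mm} exceeds one voxel")
    a = rasterize_tube(_dc.replace(spec, seed=s1))
    b = rasterize_tube(_dc.replace(spec, seed=s2), _offset_mm=shift_mm)
    return a, b


# ---------------------------------------------------------------------------
# PC-like flow phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowPhantomSpec:
    """Circular vessel with a laminar (Poiseuille) through-plane profile."""

    vessel_radius_px: int = 10
    v_max: float = 40.0          # cm/s
    venc: float = 80.0           # cm/s
    pixel_size: float = 0.45     # mm
    mag_vessel: float = 200.0
    mag_background: float = 20.0
    noise_sd: float = 4.0
    grid_shape: tuple[int, int] = (64, 64)
    seed: int = 0

    def __post_init__(self):
        if self.vessel_radius_px < 3:
            raise PhantomSpecError("vessel_radius_px must be >= 3")
        if not (0 <= self.v_max <= self.venc):
            raise PhantomSpecError(
                f"v_max ({self.v_max}) must lie in [0, VENC={self.venc}]: phase wrap is not modelled")
        if min(self.grid_shape) < 4 * self.vessel_radius_px:
            raise PhantomSpecError("grid too small for the vessel plus background")


@dataclass(frozen=True)
class FlowTruth:
    """Continuous-profile ground truth for one flow phantom."""

    flux_true: float      # ml/min
    vmax_true: float      # cm/s
    mask_true: np.ndarray

    def __post_init__(self):
        if self.flux_true < 0 or self.vmax_true < 0:
            raise PhantomSpecError("flow truth must be non-negative")


def make_pc_phantom(spec: FlowPhantomSpec) -> tuple[PhaseMagPair, FlowTruth]:
    """Poiseuille profile v(r) = v_max (1 - r^2/R^2); phase = pi v / VENC.

    The true flux is the area integral of the continuous profile,
    (pi R^2 / 100) * (v_max / 2) * 60 ml/min (mean of the parabola = v_max/2).
    """
    nx, ny = spec.grid_shape
    cx, cy = nx // 2, ny // 2
    x = np.arange(nx)[:, None] - cx
    y = np.arange(ny)[None, :] - cy
    r_px = np.hypot(x, y)
    R = float(spec.vessel_radius_px)
    inside = r_px <= R

    v = np.zeros((nx, ny))
    v[inside] = spec.v_max * (1.0 - (r_px[inside] / R) ** 2)
    phase = math.pi * v / spec.venc

    rng = np.random.default_rng(spec.seed)
    mag = np.where(inside, spec.mag_vessel, spec.mag_background).astype(float)
    if spec.noise_sd > 0:
        mag = mag + rng.normal(0.0, spec.noise_sd, size=mag.shape)

    r_mm = R * spec.pixel_size
    flux_true = (math.pi * r_mm ** 2 / 100.0) * (spec.v_max / 2.0) * 60.0
    pair = PhaseMagPair(phase=phase, magnitude=mag,
                        pixel_size=spec.pixel_size, venc=spec.venc)
    return pair, FlowTruth(flux_true=flux_true, vmax_true=spec.v_max, mask_true=inside)


# ---------------------------------------------------------------------------
# synthetic ageing cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSlopes:
    """Linear age trends of the generator (per year of age past age_range[0]).

    Defaults emulate the observed ageing pattern of the internal carotid:
    sinusoid amplitude (hence tortuosity) rises with age while peak
    velocity falls, each with Gaussian between-subject scatter.
    """

    amplitude0: float = 7.0          # mm at the youngest age
    amplitude_slope: float = 0.13    # mm / year
    amplitude_sd: float = 1.2
    vmax0: float = 36.0              # cm/s at the youngest age
    vmax_slope: float = -0.18        # cm/s / year
    vmax_sd: float = 3.5


@dataclass(frozen=True)
class CohortSubject:
    subject_id: str
    age: float
    tube_spec: TubePhantomSpec
    flow_spec: FlowPhantomSpec


def make_cohort(n: int, age_range: tuple[float, float] = (20.0, 88.0),
                slopes: CohortSlopes | None = None, seed: int = 0,
                wavelength: float = 30.0, n_periods: float = 2.0,
                tube_radius: float = 2.0,
                voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.5),
                ) -> list[CohortSubject]:
    """Deterministic synthetic cohort with age-linked geometry and flow."""
    if n < 10:
        raise PhantomSpecError(f"cohort size must be >= 10, got {n}")
    slopes = slopes or CohortSlopes()
    lo, hi = age_range
    if not lo < hi:
        raise PhantomSpecError("age_range must be increasing")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(lo, hi, size=n)
    subjects = []
    for i, age in enumerate(ages):
        amp = slopes.amplitude0 + slopes.amplitude_slope * (age - lo) \
            + rng.normal(0.0, slopes.amplitude_sd)
        vmax = slopes.vmax0 + slopes.vmax_slope * (age - lo) \
            + rng.normal(0.0, slopes.vmax_sd)
        amp = float(np.clip(amp, 1.0, None))
        vmax = float(np.clip(vmax, 5.0, 76.0))
        if amp <= 0 or vmax <= 0:
            raise PhantomSpecError("slope specification produced an invalid subject spec")
        curve = CurveSpec("sinusoid", {"amplitude": amp, "wavelength": wavelength,
                                       "n_periods": n_periods})
        tube = TubePhantomSpec(curve=curve, tube_radius=tube_radius,
                               voxel_spacing=voxel_spacing,
                               seed=int(rng.integers(0, 2 ** 31 - 1)))
        flowp = FlowPhantomSpec(v_max=vmax, seed=int(rng.integers(0, 2 ** 31 - 1)))
        subjects.append(CohortSubject(subject_id=f"S{i:03d}", age=float(age),
                                      tube_spec=tube, flow_spec=flowp))
    return subjects
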