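"""Tortuosity metrics of an arterial centerline.

Three indices quantify how far a vessel departs from a straight course:

* TI  (tortuosity index)      = AL / DL, actual over direct length;
* BL  (bending length)        = maximum perpendicular distance from the
  path to the line through its endpoints, the extent of curving in mm;
* ICM (inflection count metric) = N x TI, where N counts turning points.

N is detected automatically: after moving-average smoothing, discrete
Frenet frames are computed wherever the curvature magnitude exceeds
kappa_min, and a turning point is counted whenever the binormal jumps
between two persistent directions by more than a squared-distance
threshold (default 1.0, i.e. more than 60 degrees of rotation), with a
minimum arc-length separation between counted points.  On planar curves
this reproduces the analytic count of interior curvature-sign changes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .centerline import Centerline, resample_polyline
from .errors import DegenerateInputError, TortuflowError
from .image_io import PipelineConfig


@dataclass(frozen=True)
class TortuosityResult:
    """AL, DL, TI, BL, N and ICM for one artery."""

    al: float
    dl: float
    ti: float
    bl: float
    n: int
    icm: float

    def __post_init__(self):
        if self.dl <= 0:
            raise TortuflowError("DL must be positive")
        if self.al < self.dl * (1 - 1e-12):
            raise TortuflowError("AL cannot be smaller than DL")
        if self.bl < 0 or self.n < 0:
            raise TortuflowError("BL and N must be non-negative")
        if self.icm != self.n * self.ti:
            raise TortuflowError("ICM must equal N * TI exactly")


def _points(centerline) -> np.ndarray:
    if isinstance(centerline, Centerline):
        return centerline.points
    return np.atleast_2d(np.asarray(centerline, dtype=float))


def arc_length(centerline) -> float:
    """AL: sum of Euclidean distances between consecutive points (mm)."""
    pts = _points(centerline)
    if len(pts) < 2:
        raise DegenerateInputError("arc length requires at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def direct_length(centerline) -> float:
    """DL: Euclidean distance between the first and last points (mm)."""
    pts = _points(centerline)
    if len(pts) < 2:
        raise DegenerateInputError("direct length requires at least 2 points")
    dl = float(np.linalg.norm(pts[-1] - pts[0]))
    if dl == 0:
        raise DegenerateInputError("coincident endpoints: DL (and TI) undefined")
    return dl


def tortuosity_index(centerline) -> float:
    """TI = AL / DL (dimensionless, >= 1)."""
    return arc_length(centerline) / direct_length(centerline)


def bending_length(centerline, use_infinite_line: bool = True) -> float:
    """BL: maximum perpendicular distance from path points to the endpoint
    line (default) or to the endpoint chord segment."""
    pts = _points(centerline)
    if len(pts) < 3:
        raise DegenerateInputError("bending length requires at least 3 points")
    a, b = pts[0], pts[-1]
    chord = b - a
    chord_len = np.linalg.norm(chord)
    if chord_len == 0:
        raise DegenerateInputError("coincident endpoints: BL undefined")
    u = chord / chord_len
    rel = pts - a
    proj = rel @ u
    if not use_infinite_line:
        proj = np.clip(proj, 0.0, chord_len)
    perp = rel - proj[:, None] * u[None, :]
    return float(np.linalg.norm(perp, axis=1).max())


def smooth_polyline(points: np.ndarray, window_mm: float, step_mm: float) -> np.ndarray:
    """Moving-average smoothing with an odd window of about window_mm.

    Endpoints are pinned so DL (and hence TI) is not biased by boundary
    shrinkage of the moving average.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    w = max(int(round(window_mm / step_mm)), 1)
    if w % 2 == 0:
        w += 1
    if w <= 1 or len(pts) < w:
        return pts.copy()
    sm = uniform_filter1d(pts, size=w, axis=0, mode="nearest")
    # blend back to the exact endpoints over half a window
    half = w // 2
    for a, sl in ((0, slice(0, half + 1)), (-1, slice(len(pts) - half - 1, len(pts)))):
        weights = np.linspace(1.0, 0.0, half + 1)
        if a == -1:
            weights = weights[::-1]
        sm[sl] = weights[:, None] * pts[sl] + (1 - weights)[:, None] * sm[sl]
    return sm


def _frenet_normals(pts: np.ndarray, smooth_window: int = 1):
    """Discrete unit tangents, curvature-vector normals and curvature.

    The curvature vector (second arc-length derivative projected off the
    tangent) is optionally moving-average smoothed before normalisation:
    residual extraction jitter has near-random direction, so it cancels in
    the window mean, while the genuine normal flip at an inflection
    survives.  Curvature magnitude is taken from the same smoothed field.
    """
    d1 = np.gradient(pts, axis=0)
    speed = np.linalg.norm(d1, axis=1)
    speed = np.where(speed == 0, 1e-30, speed)
    tangent = d1 / speed[:, None]
    # curvature vector dT/ds
    kvec = np.gradient(tangent, axis=0) / speed[:, None]
    kvec = kvec - (np.sum(kvec * tangent, axis=1))[:, None] * tangent
    if smooth_window > 1:
        kvec = uniform_filter1d(kvec, size=smooth_window, axis=0, mode="nearest")
    kappa = np.linalg.norm(kvec, axis=1)
    normal = kvec / np.where(kappa == 0, 1e-30, kappa)[:, None]
    return tangent, normal, kappa


def count_turning_points(
    centerline,
    window_mm: float = 5.0,
    jump_threshold: float = 1.0,
    min_sep_mm: float = 5.0,
    kappa_min: float = 0.01,
    step_mm: float = 1.0,
    presmoothed: bool = False,
) -> int:
    """Count turning points N on a centerline resampled to a uniform step.

    Successive unit normals are compared only where curvature exceeds
    kappa_min; a squared normal jump above jump_threshold is counted as a
    turning point, with counted points at least min_sep_mm apart.
    """
    pts = _points(centerline)
    if len(pts) < 5:
        raise DegenerateInputError("turning-point count requires at least 5 points")
    sm = pts if presmoothed else smooth_polyline(pts, window_mm, step_mm)
    w = max(int(round(window_mm / step_mm)), 1)
    tangent, normal, kappa = _frenet_normals(sm, smooth_window=w)
    binormal = np.cross(tangent, normal)
    b_norm = np.linalg.norm(binormal, axis=1)
    binormal = binormal / np.where(b_norm == 0, 1e-30, b_norm)[:, None]
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(sm, axis=0), axis=1))])

    # interior only: inflections are interior points, and the first/last
    # window of a tracked centerline carries endpoint artefacts
    interior = (s >= window_mm) & (s <= s[-1] - window_mm)
    qualifying = np.nonzero((kappa > kappa_min) & interior)[0]

    # The binormal is constant along a planar arc of fixed curvature sign
    # (whatever the tangent does) and flips by 180 deg at an inflection,
    # while torsion only drifts it slowly, so turning points are counted
    # as jumps between PERSISTENT binormal directions: a candidate
    # direction must survive (as an exponential moving average following
    # torsion drift) for one smoothing window of arc length before it is
    # confirmed; jumps between successive confirmed directions exceeding
    # jump_threshold are counted, min_sep_mm apart.  Transient directions
    # from residual extraction jitter never confirm and are ignored.
    persist_mm = window_mm
    count = 0
    ref = None
    cand = None
    cand_start = 0.0
    confirmed = False
    last_counted_s = -np.inf
    prev_s = None
    for i in qualifying:
        v, si = binormal[i], s[i]
        if cand is not None and float(np.sum((v - cand) ** 2)) <= jump_threshold:
            alpha = min((si - prev_s) / persist_mm, 1.0) if prev_s is not None else 1.0
            cand = cand + alpha * (v - cand)
            cand = cand / np.linalg.norm(cand)
        else:
            cand = v.copy()
            cand_start = si
            confirmed = False
        if not confirmed and si - cand_start >= persist_mm:
            confirmed = True
            if ref is not None and float(np.sum((cand - ref) ** 2)) > jump_threshold \
                    and si - last_counted_s >= min_sep_mm:
                count += 1
                last_counted_s = si
        if confirmed:
            ref = cand
        prev_s = si
    return count


def inflection_count_metric(ti: float, n: int) -> float:
    """ICM = N x TI, exact."""
    if ti < 1 - 1e-12:
        raise TortuflowError(f"TI must be >= 1, got {ti}")
    if n < 0:
        raise TortuflowError("N must be non-negative")
    return n * ti


def summarize(centerline, config: PipelineConfig | None = None) -> TortuosityResult:
    """All six metrics from the same resampled and smoothed curve."""
    cfg = config or PipelineConfig()
    pts = resample_polyline(_points(centerline), cfg.resample_step_mm)
    if len(pts) < 5:
        raise DegenerateInputError("centerline too short to summarise")
    sm = smooth_polyline(pts, cfg.smoothing_window_mm, cfg.resample_step_mm)
    al = arc_length(sm)
    dl = direct_length(sm)
    ti = max(al / dl, 1.0)  # guard against eps-level AL < DL on straight lines
    bl = bending_length(sm, use_infinite_line=cfg.bl_use_infinite_line)
    n = count_turning_points(
        sm,
        window_mm=cfg.smoothing_window_mm,
        jump_threshold=cfg.normal_jump_threshold,
        min_sep_mm=cfg.min_inflection_sep_mm,
        kappa_min=cfg.kappa_min,
        step_mm=cfg.resample_step_mm,
        presmoothed=True,
    )
    return TortuosityResult(al=al, dl=dl, ti=ti, bl=bl, n=n, icm=n * ti)
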