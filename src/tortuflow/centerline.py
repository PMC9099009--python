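"""Centerline extraction by multi-stencils fast marching.

The segmented artery is turned into a medialness speed map from the
anisotropic Euclidean distance transform, the Eikonal equation
|grad T| * F = 1 is solved by fast marching over multiple stencils
(axis-aligned plus in-plane diagonal stencils, second-order upwind
differences where two accepted upwind values are available), and the
centerline is recovered by gradient descent on the arrival time from
the target back to the source.

The distance-transform speed F = (EDT / max EDT)^gamma makes travel along
the vessel axis much cheaper than near the wall, so the minimal path runs
through the centres of the level curves of the front -- the skeleton of
the artery.
"""
from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .errors import (
    ComplicatedGeometryError,
    ConvergenceError,
    DegenerateInputError,
    TortuflowError,
    UnreachableError,
)
from .segmentation import VesselMask, link_components

logger = logging.getLogger("tortuflow")

_FAR, _TRIAL, _KNOWN = 0, 1, 2


@dataclass(frozen=True)
class SpeedMap:
    """Non-negative front speed F(x); zero outside the vessel mask."""

    data: np.ndarray
    spacing: tuple[float, float, float]


@dataclass(frozen=True)
class ArrivalTime:
    """First-arrival times from the source; +inf where unreached."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    source: tuple[int, int, int]


@dataclass(frozen=True)
class Centerline:
    """Ordered 3-D points in physical mm coordinates, source to target."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise TortuflowError("Centerline points must be an (N, 3) array")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


def medialness_speed(mask: VesselMask, gamma: float = 2.0) -> SpeedMap:
    """F(x) = (EDT(x) / max EDT)^gamma inside the mask, 0 outside."""
    if not mask.data.any():
        raise DegenerateInputError("cannot build a speed map from an empty mask")
    edt = ndimage.distance_transform_edt(mask.data, sampling=mask.spacing)
    speed = np.zeros_like(edt)
    inside = mask.data
    speed[inside] = (edt[inside] / edt.max()) ** gamma
    return SpeedMap(speed, mask.spacing)


def _stencils(spacing):
    """Stencils of mutually orthogonal physical directions.

    Always the axis stencil; a diagonal stencil is added for each
    coordinate plane with equal spacing (diagonals are orthogonal in
    physical space only then).
    """
    dx, dy, dz = spacing
    st = [(((1, 0, 0), dx), ((0, 1, 0), dy), ((0, 0, 1), dz))]
    if math.isclose(dx, dy):
        h = math.hypot(dx, dy)
        st.append((((1, 1, 0), h), ((1, -1, 0), h), ((0, 0, 1), dz)))
    if math.isclose(dx, dz):
        h = math.hypot(dx, dz)
        st.append((((1, 0, 1), h), ((1, 0, -1), h), ((0, 1, 0), dy)))
    if math.isclose(dy, dz):
        h = math.hypot(dy, dz)
        st.append((((0, 1, 1), h), ((0, 1, -1), h), ((1, 0, 0), dx)))
    return st


def _solve_quadratic(contribs, inv_f2):
    """Largest root of sum_i (a_i T - b_i)^2 = inv_f2, or None."""
    A = sum(a * a for a, b, _ in contribs)
    B = -2.0 * sum(a * b for a, b, _ in contribs)
    C = sum(b * b for a, b, _ in contribs) - inv_f2
    disc = B * B - 4.0 * A * C
    if disc < 0:
        return None
    return (-B + math.sqrt(disc)) / (2.0 * A)


def fast_march(speed: SpeedMap, source: tuple[int, int, int]) -> ArrivalTime:
    """Solve |grad T| * F = 1 from a single source voxel.

    Second-order upwind differences are used on each stencil direction
    where two accepted upwind values are available; the immediate
    neighbourhood of the source is initialised with local analytic
    distances to remove the point-source error.
    """
    F = np.asarray(speed.data, dtype=float)
    spacing = speed.spacing
    src = tuple(int(i) for i in source)
    if F[src] <= 0:
        raise TortuflowError(f"source voxel {src} has non-positive speed")
    shape = F.shape
    sp = np.asarray(spacing)

    stencils = _stencils(spacing)
    relax_dirs = sorted({d for st in stencils for (v, _) in st for d in (v, tuple(-c for c in v))})

    T = np.full(shape, np.inf)
    state = np.zeros(shape, dtype=np.uint8)
    heap: list[tuple[float, tuple[int, int, int]]] = []

    def in_bounds(idx):
        return all(0 <= idx[a] < shape[a] for a in range(3))

    def update(idx):
        """Minimum over stencils of the upwind Eikonal solution at idx."""
        inv_f2 = 1.0 / (F[idx] * F[idx])
        best = math.inf
        for stencil in stencils:
            contribs = []
            for v, h in stencil:
                t1 = math.inf
                sgn_best = 0
                for sgn in (1, -1):
                    n = (idx[0] + sgn * v[0], idx[1] + sgn * v[1], idx[2] + sgn * v[2])
                    if in_bounds(n) and state[n] == _KNOWN and T[n] < t1:
                        t1 = T[n]
                        sgn_best = sgn
                if not math.isfinite(t1):
                    continue
                n2 = (idx[0] + 2 * sgn_best * v[0], idx[1] + 2 * sgn_best * v[1],
                      idx[2] + 2 * sgn_best * v[2])
                if in_bounds(n2) and state[n2] == _KNOWN and T[n2] <= t1:
                    t2 = T[n2]
                    contribs.append((1.5 / h, (2.0 * t1 - 0.5 * t2) / h, t1))
                else:
                    contribs.append((1.0 / h, t1 / h, t1))
            # causality: the solution must not be smaller than any value used
            while contribs:
                root = _solve_quadratic(contribs, inv_f2)
                if root is not None and all(root >= c[2] for c in contribs):
                    if root < best:
                        best = root
                    break
                if len(contribs) == 1:
                    a, b, t1 = contribs[0]
                    cand = t1 + (1.0 / (a * F[idx]))  # first-order single direction
                    if cand < best:
                        best = cand
                    break
                contribs.remove(max(contribs, key=lambda c: c[2]))
        return best

    T[src] = 0.0
    heapq.heappush(heap, (0.0, src))
    # factored-source initialisation: seed exact local arrival times in a
    # 2-voxel ball around the source (harmonic-mean local speed)
    for off in product((-2, -1, 0, 1, 2), repeat=3):
        if off == (0, 0, 0):
            continue
        n = (src[0] + off[0], src[1] + off[1], src[2] + off[2])
        if not in_bounds(n) or F[n] <= 0:
            continue
        d = float(np.linalg.norm(np.asarray(off) * sp))
        f_loc = 2.0 / (1.0 / F[src] + 1.0 / F[n])
        t = d / f_loc
        if t < T[n]:
            T[n] = t
            state[n] = _TRIAL
            heapq.heappush(heap, (t, n))

    while heap:
        t, idx = heapq.heappop(heap)
        if state[idx] == _KNOWN or t > T[idx]:
            continue
        state[idx] = _KNOWN
        for v in relax_dirs:
            n = (idx[0] + v[0], idx[1] + v[1], idx[2] + v[2])
            if not in_bounds(n) or state[n] == _KNOWN or F[n] <= 0:
                continue
            nt = update(n)
            if nt < T[n]:
                T[n] = nt
                state[n] = _TRIAL
                heapq.heappush(heap, (nt, n))

    T[state != _KNOWN] = np.inf
    return ArrivalTime(T, spacing, src)


def backtrace(arrival: ArrivalTime, target: tuple[int, int, int],
              step: float | None = None) -> Centerline:
    """Gradient descent on the arrival time from target to source.

    Second-order (midpoint) integration of the normalised negative
    gradient, trilinear interpolation of the gradient field, with a
    discrete steepest-neighbour fallback at stagnation points.  Returned
    points are ordered source -> target, in physical mm.
    """
    T = arrival.data
    spacing = np.asarray(arrival.spacing)
    tgt = tuple(int(i) for i in target)
    if not math.isfinite(T[tgt]):
        raise UnreachableError(f"target voxel {tgt} was not reached by the front")
    src_mm = np.asarray(arrival.source) * spacing
    tgt_mm = np.asarray(tgt) * spacing
    if tgt == arrival.source:
        return Centerline(src_mm[None, :])

    if step is None:
        step = 0.4 * float(spacing.min())
    finite = np.isfinite(T)
    t_max = T[finite].max()
    fill = t_max * 1.5 + 10.0 * float(spacing.max())
    T_fill = np.where(finite, T, fill)

    axes = [np.arange(n) * s for n, s in zip(T.shape, spacing)]
    grads = np.gradient(T_fill, *spacing)
    g_interp = [RegularGridInterpolator(axes, g, bounds_error=False, fill_value=None)
                for g in grads]
    t_interp = RegularGridInterpolator(axes, T_fill, bounds_error=False, fill_value=None)
    hi_mm = np.array([(n - 1) * s for n, s in zip(T.shape, spacing)])

    def grad_at(p):
        return np.array([gi(p).item() for gi in g_interp])

    def clip(p):
        return np.clip(p, 0.0, hi_mm)

    pos = tgt_mm.astype(float)
    pts = [pos.copy()]
    cur_t = t_interp(pos).item()
    stop_dist = max(step, float(spacing.max()))
    max_steps = 10 * int(finite.sum()) + 100

    for _ in range(max_steps):
        if np.linalg.norm(pos - src_mm) <= stop_dist:
            break
        moved = False
        g = grad_at(pos)
        gn = np.linalg.norm(g)
        if gn > 1e-12:
            mid = clip(pos - 0.5 * step * g / gn)
            g2 = grad_at(mid)
            g2n = np.linalg.norm(g2)
            if g2n > 1e-12:
                cand = clip(pos - step * g2 / g2n)
            else:
                cand = clip(pos - step * g / gn)
            cand_t = t_interp(cand).item()
            if cand_t < cur_t - 1e-12:
                pos, cur_t, moved = cand, cand_t, True
        if not moved:
            # steepest-descent fallback on the voxel grid.  Every accepted
            # fast-marching voxel has a strictly lower 26-neighbour, so
            # walking to the lowest neighbour always makes progress and
            # cannot cycle; intermediate points keep segments <= step
            vox = np.rint(pos / spacing).astype(int)
            vox = np.clip(vox, 0, np.asarray(T.shape) - 1)
            best, best_t = None, T_fill[tuple(vox)]
            for off in product((-1, 0, 1), repeat=3):
                n = tuple(vox + off)
                if all(0 <= n[a] < T.shape[a] for a in range(3)) and T_fill[n] < best_t:
                    best, best_t = n, T_fill[n]
            if best is None:
                raise ConvergenceError(
                    "backtrace stagnated away from the source "
                    f"(position {pos.tolist()}, arrival {cur_t:.3f})"
                )
            goal = np.asarray(best) * spacing
            dist = np.linalg.norm(goal - pos)
            n_sub = max(int(math.ceil(dist / step)), 1)
            for k in range(1, n_sub):
                pts.append(pos + (goal - pos) * k / n_sub)
            pos = goal
            cur_t = float(best_t)
        pts.append(pos.copy())
    else:
        raise ConvergenceError("backtrace exceeded the step budget without reaching the source")

    pts.append(src_mm.astype(float))
    return Centerline(np.asarray(pts[::-1]))


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline to uniform arc-length spacing (endpoints kept)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 2:
        return points.copy()
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return points[:1].copy()
    n = max(int(math.ceil(total / step - 1e-9)), 1)  # segments never exceed step
    targets = np.linspace(0.0, total, n + 1)
    return np.column_stack([np.interp(targets, s, points[:, a]) for a in range(3)])


def _auto_endpoints(mask: VesselMask) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """Source/target = mask voxel nearest the centroid of the lowest/highest
    occupied slice (neck arteries run head-foot through the slab)."""
    occupied = np.nonzero(mask.data)
    zs = occupied[2]
    z_lo, z_hi = int(zs.min()), int(zs.max())
    if z_lo == z_hi:
        raise ComplicatedGeometryError(
            "mask occupies a single slice; endpoints cannot be placed on the slice axis"
        )

    def slice_point(z):
        xs, ys = np.nonzero(mask.data[:, :, z])
        cx, cy = xs.mean(), ys.mean()
        k = int(np.argmin((xs - cx) ** 2 + (ys - cy) ** 2))
        return (int(xs[k]), int(ys[k]), z)

    return slice_point(z_lo), slice_point(z_hi)


def nearest_mask_voxel(mask: VesselMask, point_mm) -> tuple[int, int, int]:
    """Snap a physical point to the nearest mask voxel (for seed placement)."""
    if not mask.data.any():
        raise DegenerateInputError("empty mask")
    idx = np.column_stack(np.nonzero(mask.data)).astype(float)
    sp = np.asarray(mask.spacing)
    d2 = np.sum((idx * sp - np.asarray(point_mm, dtype=float)) ** 2, axis=1)
    best = idx[int(np.argmin(d2))]
    return tuple(int(v) for v in best)


def extract_centerline(
    mask: VesselMask,
    source: tuple[int, int, int] | None = None,
    target: tuple[int, int, int] | None = None,
    gamma: float = 2.0,
    resample_step: float = 1.0,
    descent_step_factor: float = 0.4,
) -> Centerline:
    """Medialness speed -> fast march -> backtrace, resampled to a uniform
    arc-length step.  Endpoints default to the extreme-slice centroids."""
    labels, sizes = link_components(mask)
    if sizes.size != 1:
        raise TortuflowError(
            f"centerline extraction requires a single connected component, got {sizes.size}"
        )
    if source is None or target is None:
        auto_src, auto_tgt = _auto_endpoints(mask)
        source = source or auto_src
        target = target or auto_tgt
    for name, pt in (("source", source), ("target", target)):
        if not mask.data[tuple(int(i) for i in pt)]:
            raise TortuflowError(f"{name} voxel {tuple(pt)} lies outside the mask")
    # threshold noise can knock isolated interior voxels out of the lumen;
    # enclosed holes would force the medial path to detour around them
    filled = ndimage.binary_fill_holes(mask.data)
    if filled.sum() != mask.data.sum():
        mask = VesselMask(filled, mask.spacing)
    speed = medialness_speed(mask, gamma=gamma)
    arrival = fast_march(speed, source)
    step = descent_step_factor * min(mask.spacing)
    path = backtrace(arrival, target, step=step)
    # light moving average (two voxels of arc) removes sub-voxel descent
    # jitter before resampling; shortening of true geometry is O(w^2/R^2),
    # negligible at vessel-scale curvature radii
    from .tortuosity import smooth_polyline
    smoothed = smooth_polyline(path.points, 2.0 * min(mask.spacing), step)
    return Centerline(resample_polyline(smoothed, resample_step))
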