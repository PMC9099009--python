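"""Eikonal solver, backtrace and centerline extraction."""
import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

import tortuflow as tf
from tortuflow.centerline import _auto_endpoints, nearest_mask_voxel
from tortuflow.errors import (
    ComplicatedGeometryError,
    DegenerateInputError,
    TortuflowError,
    UnreachableError,
)
from tests.conftest import segment_and_track


def _uniform_arrival_21():
    speed = tf.SpeedMap(np.ones((21, 21, 21)), (1.0, 1.0, 1.0))
    return tf.fast_march(speed, (10, 10, 10))


@pytest.fixture(scope="module")
def uniform_arrival():
    return _uniform_arrival_21()


def dijkstra_geodesic(speed_grid, spacing, src, tgt):
    """Independent oracle: 26-neighbour graph with Euclidean edge weights."""
    idx = np.argwhere(speed_grid > 0)
    pos = {tuple(p): i for i, p in enumerate(idx)}
    offs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)]
    sp = np.asarray(spacing)
    rows, cols, vals = [], [], []
    for i, p in enumerate(idx):
        for o in offs:
            q = tuple(p + o)
            if q in pos:
                rows.append(i)
                cols.append(pos[q])
                vals.append(float(np.linalg.norm(np.asarray(o) * sp)))
    g = coo_matrix((vals, (rows, cols)), shape=(len(idx), len(idx))).tocsr()
    return dijkstra(g, indices=pos[tuple(src)])[pos[tuple(tgt)]]


class TestMedialnessSpeed:
    def test_constant_along_single_voxel_line(self):
        data = np.zeros((9, 9, 9), dtype=bool)
        data[4, 4, 1:8] = True
        speed = tf.medialness_speed(tf.VesselMask(data, (1, 1, 1)))
        vals = speed.data[4, 4, 1:8]
        assert np.allclose(vals, vals[0]) and vals[0] > 0

    def test_zero_outside_positive_inside(self, straight_phantom):
        speed = tf.medialness_speed(straight_phantom.true_mask)
        assert np.all(speed.data[~straight_phantom.true_mask.data] == 0)
        assert np.all(speed.data[straight_phantom.true_mask.data] > 0)

    def test_cylinder_slice_argmax_on_axis(self):
        data = np.zeros((15, 15, 20), dtype=bool)
        ii, jj = np.meshgrid(np.arange(15), np.arange(15), indexing="ij")
        disc = (ii - 7) ** 2 + (jj - 7) ** 2 <= 9
        data[:, :, 2:18] = disc[:, :, None]
        speed = tf.medialness_speed(tf.VesselMask(data, (1, 1, 1)))
        for z in range(5, 15):
            assert np.unravel_index(np.argmax(speed.data[:, :, z]), (15, 15)) == (7, 7)

    def test_gamma_preserves_argmax(self):
        data = np.zeros((11, 11, 11), dtype=bool)
        data[3:8, 3:8, 3:8] = True
        m = tf.VesselMask(data, (1, 1, 1))
        s2 = tf.medialness_speed(m, gamma=2.0)
        s4 = tf.medialness_speed(m, gamma=4.0)
        assert np.argmax(s2.data) == np.argmax(s4.data)

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            tf.medialness_speed(tf.VesselMask(np.zeros((3, 3, 3), bool), (1, 1, 1)))


class TestFastMarch:
    def test_uniform_speed_arrival_matches_euclidean_distance(self, uniform_arrival):
        ii, jj, kk = np.meshgrid(*[np.arange(21)] * 3, indexing="ij")
        d = np.sqrt((ii - 10.0) ** 2 + (jj - 10.0) ** 2 + (kk - 10.0) ** 2)
        assert np.abs(uniform_arrival.data - d).max() <= 1.0  # one voxel spacing

    def test_source_arrival_exactly_zero(self, uniform_arrival):
        assert uniform_arrival.data[10, 10, 10] == 0.0

    def test_disconnected_region_unreached(self):
        speed = np.zeros((9, 9, 9))
        speed[1:3, 1:3, 1:3] = 1.0
        speed[6:8, 6:8, 6:8] = 1.0
        arr = tf.fast_march(tf.SpeedMap(speed, (1, 1, 1)), (1, 1, 1))
        assert np.isinf(arr.data[7, 7, 7])
        assert np.isfinite(arr.data[2, 2, 2])

    def test_anisotropic_spacing_honoured(self):
        speed = tf.SpeedMap(np.ones((9, 9, 9)), (1.0, 1.0, 1.5))
        arr = tf.fast_march(speed, (4, 4, 4))
        assert arr.data[4, 4, 6] == pytest.approx(3.0, abs=0.15)  # 2 voxels x 1.5 mm
        assert arr.data[6, 4, 4] == pytest.approx(2.0, abs=0.15)

    def test_source_outside_support_rejected(self):
        speed = np.zeros((5, 5, 5))
        speed[2, 2, 2] = 1.0
        with pytest.raises(TortuflowError, match="source"):
            tf.fast_march(tf.SpeedMap(speed, (1, 1, 1)), (0, 0, 0))


class TestBacktrace:
    def test_target_equals_source_single_point(self, uniform_arrival):
        path = tf.backtrace(uniform_arrival, (10, 10, 10))
        assert len(path) == 1

    def test_straight_corridor_path_near_axis(self):
        speed = np.zeros((7, 7, 40))
        speed[2:5, 2:5, 1:39] = 1.0
        arr = tf.fast_march(tf.SpeedMap(speed, (1, 1, 1)), (3, 3, 2))
        path = tf.backtrace(arr, (3, 3, 37))
        lateral = np.linalg.norm(path.points[:, :2] - [3.0, 3.0], axis=1)
        assert lateral.max() <= 1.0
        length = np.linalg.norm(np.diff(path.points, axis=0), axis=1).sum()
        assert length == pytest.approx(35.0, rel=0.02)

    def test_l_corridor_length_matches_dijkstra_oracle(self):
        speed = np.zeros((40, 40, 40))
        w = 5
        speed[2:2 + w, 2:2 + w, 2:30] = 1.0
        speed[2:30, 2:2 + w, 25:25 + w] = 1.0
        src, tgt = (4, 4, 3), (28, 4, 27)
        arr = tf.fast_march(tf.SpeedMap(speed, (1, 1, 1)), src)
        path = tf.backtrace(arr, tgt)
        length = np.linalg.norm(np.diff(path.points, axis=0), axis=1).sum()
        oracle = dijkstra_geodesic(speed, (1, 1, 1), src, tgt)
        assert length == pytest.approx(oracle, rel=0.05)

    def test_unreachable_target_rejected(self):
        speed = np.zeros((9, 9, 9))
        speed[1:3, 1:3, 1:3] = 1.0
        speed[6:8, 6:8, 6:8] = 1.0
        arr = tf.fast_march(tf.SpeedMap(speed, (1, 1, 1)), (1, 1, 1))
        with pytest.raises(UnreachableError):
            tf.backtrace(arr, (7, 7, 7))

    def test_arrival_decreases_monotonically_along_path(self, straight_phantom):
        mask = straight_phantom.true_mask
        src, tgt = _auto_endpoints(mask)
        arr = tf.fast_march(tf.medialness_speed(mask), src)
        path = tf.backtrace(arr, tgt, step=0.4)
        from scipy.interpolate import RegularGridInterpolator
        axes = [np.arange(n) * s for n, s in zip(arr.data.shape, arr.spacing)]
        finite_max = arr.data[np.isfinite(arr.data)].max()
        interp = RegularGridInterpolator(axes, np.where(np.isfinite(arr.data), arr.data,
                                                        finite_max * 2))
        t_vals = interp(path.points)  # ordered source -> target
        assert np.all(np.diff(t_vals) > -1e-9)

    def test_path_length_at_least_direct_length(self, straight_phantom):
        mask = straight_phantom.true_mask
        src, tgt = _auto_endpoints(mask)
        arr = tf.fast_march(tf.medialness_speed(mask), src)
        path = tf.backtrace(arr, tgt, step=0.4)
        length = np.linalg.norm(np.diff(path.points, axis=0), axis=1).sum()
        assert length >= np.linalg.norm(path.points[-1] - path.points[0]) - 1e-12


class TestExtractCenterline:
    def test_straight_tube_centerline_on_axis(self, straight_phantom):
        cl = segment_and_track(straight_phantom)
        axis_xy = straight_phantom.truth.points[0, :2]
        radial = np.linalg.norm(cl.points[:, :2] - axis_xy, axis=1)
        assert radial.max() <= 1.0  # one voxel

    def test_helix_arc_length_within_three_percent(self, helix_phantom):
        cl = segment_and_track(helix_phantom, truth_endpoints=True)
        al = np.linalg.norm(np.diff(cl.points, axis=0), axis=1).sum()
        assert al == pytest.approx(helix_phantom.truth.al_true, rel=0.03)

    def test_centrality_mean_deviation_below_voxel(self, helix_phantom):
        from scipy.spatial import cKDTree
        cl = segment_and_track(helix_phantom, truth_endpoints=True)
        dense = tf.make_curve(helix_phantom.spec.curve, n_points=8000).points
        dense = dense + (helix_phantom.truth.points[0] - dense[0])
        d, _ = cKDTree(dense).query(cl.points)
        assert d.mean() <= 1.0

    def test_consecutive_spacing_bounded(self, straight_phantom):
        cl = segment_and_track(straight_phantom)
        seg = np.linalg.norm(np.diff(cl.points, axis=0), axis=1)
        assert seg.max() <= max(straight_phantom.volume.spacing) + 1e-6

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            tf.extract_centerline(tf.VesselMask(np.zeros((4, 4, 4), bool), (1, 1, 1)))

    def test_single_slice_mask_is_complicated_geometry(self):
        data = np.zeros((10, 10, 5), dtype=bool)
        data[2:8, 2:8, 2] = True
        with pytest.raises(ComplicatedGeometryError):
            tf.extract_centerline(tf.VesselMask(data, (1, 1, 1)))

    def test_multi_component_mask_rejected(self):
        data = np.zeros((10, 10, 10), dtype=bool)
        data[1:3, 1:3, :] = True
        data[7:9, 7:9, :] = True
        with pytest.raises(TortuflowError, match="single"):
            tf.extract_centerline(tf.VesselMask(data, (1, 1, 1)))

    def test_nearest_mask_voxel_snaps_inside(self, straight_phantom):
        v = nearest_mask_voxel(straight_phantom.true_mask, straight_phantom.truth.points[0])
        assert straight_phantom.true_mask.data[v]
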