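"""Shared phantom fixtures (generated at test time; session-scoped where heavy)."""
import numpy as np
import pytest

import tortuflow as tf
from tortuflow.pipeline import suggest_roi


@pytest.fixture(scope="session")
def straight_phantom():
    """Straight tube, radius 2 mm, length 100 mm, 1 mm isotropic, SNR ~ 10."""
    spec = tf.TubePhantomSpec(
        curve=tf.CurveSpec("straight", {"length": 100.0}),
        tube_radius=2.0, voxel_spacing=(1.0, 1.0, 1.0),
        fg_intensity=200.0, bg_mean=100.0, noise_sd=10.0, seed=1,
    )
    return tf.rasterize_tube(spec)


@pytest.fixture(scope="session")
def straight_segmented(straight_phantom):
    roi = suggest_roi(straight_phantom)
    j_star, mask = tf.select_j(straight_phantom.volume, roi)
    return roi, j_star, mask


@pytest.fixture(scope="session")
def semicircle_phantom():
    spec = tf.TubePhantomSpec(
        curve=tf.CurveSpec("semicircle", {"radius": 20.0}),
        tube_radius=2.0, voxel_spacing=(1.0, 1.0, 1.0), seed=2,
    )
    return tf.rasterize_tube(spec)


@pytest.fixture(scope="session")
def helix_phantom():
    spec = tf.TubePhantomSpec(
        curve=tf.CurveSpec("helix", {"radius": 10.0, "pitch": 20.0, "n_turns": 2}),
        tube_radius=2.0, voxel_spacing=(1.0, 1.0, 1.0), seed=3,
    )
    return tf.rasterize_tube(spec)


def segment_and_track(phantom, truth_endpoints=False):
    """Helper: full segmentation + centerline for a tube phantom."""
    roi = suggest_roi(phantom)
    _, mask = tf.select_j(phantom.volume, roi)
    kwargs = {}
    if truth_endpoints:
        kwargs["source"] = tf.centerline.nearest_mask_voxel(mask, phantom.truth.points[0])
        kwargs["target"] = tf.centerline.nearest_mask_voxel(mask, phantom.truth.points[-1])
    return tf.extract_centerline(mask, **kwargs)
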