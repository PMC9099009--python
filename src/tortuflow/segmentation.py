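"""Intensity-statistics artery segmentation with automatic j selection.

A preliminary ROI Omega encloses the target artery plus surrounding
tissue.  Artery voxels are those whose intensity exceeds mu + j*sigma,
where mu and sigma are the mean and (population) standard deviation of
Omega.  j is searched downward from j_max until the largest connected
component spans the ROI's full slice extent -- the observable property
of an intact neck artery crossing the imaging slab.  Components are
linked under 18-connectivity: voxels touching by faces or edges belong
together, corner-only contact does not.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu as _skimage_otsu

from .errors import DegenerateInputError, SegmentationError, TortuflowError
from .image_io import ROIBox, Volume3D

logger = logging.getLogger("tortuflow")

#: faces + edges (18-connectivity) structuring element
STRUCTURE_18 = ndimage.generate_binary_structure(3, 2)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class RegionStats:
    """Mean and population standard deviation of the ROI Omega."""

    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise TortuflowError("sigma must be non-negative")


@dataclass(frozen=True)
class VesselMask:
    """Binary artery mask aligned to its parent volume."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    connectivity: int = 18

    def __post_init__(self):
        data = np.asarray(self.data, dtype=bool)
        if data.ndim != 3:
            raise TortuflowError("VesselMask requires a 3-D grid")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def region_stats(volume: Volume3D, roi: ROIBox) -> RegionStats:
    """mu and sigma over all ROI voxels (population standard deviation)."""
    roi.check_within(volume.shape)
    values = np.asarray(volume.data[roi.slices], dtype=float)
    if values.size == 0:
        raise DegenerateInputError("empty ROI")
    return RegionStats(mu=float(values.mean()), sigma=float(values.std()))


def threshold_arteries(volume: Volume3D, roi: ROIBox, stats: RegionStats, j: float) -> VesselMask:
    """Voxels in the ROI with I(x) > mu + j*sigma; everything outside is false."""
    if j < 0:
        raise TortuflowError(f"j must be >= 0, got {j}")
    if stats.sigma == 0:
        raise DegenerateInputError("ROI has zero intensity variance (no contrast)")
    roi.check_within(volume.shape)
    cutoff = stats.mu + j * stats.sigma
    mask = np.zeros(volume.shape, dtype=bool)
    mask[roi.slices] = volume.data[roi.slices] > cutoff
    return VesselMask(mask, volume.spacing)


def otsu_threshold(volume: Volume3D, roi: ROIBox) -> VesselMask:
    """Alternative segmentation mode: Otsu's threshold over the ROI."""
    roi.check_within(volume.shape)
    values = np.asarray(volume.data[roi.slices], dtype=float)
    if values.size == 0:
        raise DegenerateInputError("empty ROI")
    if values.min() == values.max():
        raise DegenerateInputError("ROI has zero intensity variance (no contrast)")
    cutoff = _skimage_otsu(values)
    mask = np.zeros(volume.shape, dtype=bool)
    mask[roi.slices] = volume.data[roi.slices] > cutoff
    return VesselMask(mask, volume.spacing)


def link_components(mask: VesselMask) -> tuple[np.ndarray, np.ndarray]:
    """Label 3-D connected components (default 18-connectivity).

    Returns ``(labels, sizes)`` where ``labels`` is an int grid with 0 as
    background and ``sizes[k]`` is the voxel count of label ``k + 1``.
    """
    if not mask.data.any():
        raise DegenerateInputError("cannot link components of an empty mask")
    structure = _STRUCTURES[mask.connectivity]
    labels, n = ndimage.label(mask.data, structure=structure)
    sizes = np.bincount(labels.ravel())[1:]
    logger.debug("link_components: %d components, sizes %s", n, sizes.tolist())
    return labels, sizes


def _component_spans_roi(labels: np.ndarray, label: int, roi: ROIBox) -> bool:
    """True if the component occupies every slice of the ROI's z extent."""
    zs = np.unique(np.nonzero(labels == label)[2])
    if zs.size == 0:
        return False
    # 18-connectivity steps change z by at most 1, so the occupied z range
    # of a connected component is contiguous: checking the extremes suffices.
    return zs.min() <= roi.lower[2] and zs.max() >= roi.upper[2] - 1


def select_j(
    volume: Volume3D,
    roi: ROIBox,
    j_max: float = 6.0,
    j_min: float = 4.0,
    j_step: float = 0.25,
) -> tuple[float, VesselMask]:
    """Search j downward from j_max; accept the first value whose largest
    component spans the ROI's slice extent.  Returns (j_star, component mask).
    """
    if j_min > j_max:
        raise TortuflowError(f"j_min ({j_min}) must not exceed j_max ({j_max})")
    stats = region_stats(volume, roi)
    n_steps = int(np.floor((j_max - j_min) / j_step + 1e-9))
    for k in range(n_steps + 1):
        j = j_max - k * j_step
        mask = threshold_arteries(volume, roi, stats, j)
        if not mask.data.any():
            continue
        labels, sizes = link_components(mask)
        # candidate components in decreasing size order
        for label in np.argsort(sizes)[::-1] + 1:
            if _component_spans_roi(labels, int(label), roi):
                selected = VesselMask(labels == label, volume.spacing)
                logger.info("select_j: accepted j=%.2f, component size %d voxels",
                            j, selected.n_voxels)
                return float(j), selected
            break  # only the largest component is considered
    raise SegmentationError(
        f"segmentation failed: no j in [{j_min}, {j_max}] yields a component "
        "spanning the ROI slice extent"
    )


def select_artery(
    labels: np.ndarray,
    spacing,
    seed_point: tuple[int, int, int] | None = None,
    roi: ROIBox | None = None,
) -> VesselMask:
    """Pick one labelled component: by seed point, else the largest spanning
    (or simply largest) component."""
    sizes = np.bincount(labels.ravel())[1:]
    if sizes.size == 0:
        raise DegenerateInputError("no labelled components")
    if seed_point is not None:
        label = int(labels[tuple(int(i) for i in seed_point)])
        if label == 0:
            raise SegmentationError(f"seed point {tuple(seed_point)} lies in the background")
        return VesselMask(labels == label, spacing)
    order = np.argsort(sizes)[::-1] + 1
    if roi is not None:
        for label in order:
            if _component_spans_roi(labels, int(label), roi):
                return VesselMask(labels == int(label), spacing)
    return VesselMask(labels == int(order[0]), spacing)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) between two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        raise DegenerateInputError("both masks are empty")
    return 2.0 * np.logical_and(a, b).sum() / float(denom)
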