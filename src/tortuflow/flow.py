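"""Phase-contrast flow quantification: flux, MaxV, unit-mass CBF, CoV.

A through-plane velocity map is obtained from the phase image as
v = VENC * phase / pi (phase in radians, |phase| <= pi).  The vessel mask
is formed on the magnitude image by thresholding at ``noise_multiplier``
(default 5) times the mean background magnitude, the flux is the signed
velocity sum over the mask converted to ml/min, and MaxV is the largest
absolute velocity inside the mask.  Unit-mass CBF sums the four feeding
arteries' fluxes and normalises by brain parenchyma mass.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, NoVesselSignalError, TortuflowError

_PHASE_TOL = 1e-9


@dataclass(frozen=True)
class PhaseMagPair:
    """Phase (radians) and magnitude images with pixel size (mm) and VENC (cm/s)."""

    phase: np.ndarray
    magnitude: np.ndarray
    pixel_size: float
    venc: float

    def __post_init__(self):
        phase = np.asarray(self.phase, dtype=float)
        mag = np.asarray(self.magnitude, dtype=float)
        if phase.ndim != 2 or phase.shape != mag.shape:
            raise TortuflowError("phase and magnitude must be 2-D arrays of equal shape")
        if self.venc <= 0 or self.pixel_size <= 0:
            raise TortuflowError("VENC and pixel size must be positive")
        object.__setattr__(self, "phase", phase)
        object.__setattr__(self, "magnitude", mag)


@dataclass(frozen=True)
class FlowResult:
    """Flux (ml/min), maximum velocity (cm/s) and vessel-mask pixel count."""

    flux: float
    max_velocity: float
    mask_pixel_count: int

    def __post_init__(self):
        if self.flux < 0 or self.max_velocity < 0 or self.mask_pixel_count < 1:
            raise TortuflowError("invalid FlowResult fields")


def _region_mask(region, shape) -> np.ndarray:
    """Accept a boolean mask or an (x0, y0, x1, y1) half-open box."""
    if region is None:
        return np.ones(shape, dtype=bool)
    region_arr = np.asarray(region)
    if region_arr.dtype == bool:
        if region_arr.shape != shape:
            raise TortuflowError("region mask shape mismatch")
        return region_arr
    x0, y0, x1, y1 = (int(v) for v in region_arr.ravel())
    if not (0 <= x0 < x1 <= shape[0] and 0 <= y0 < y1 <= shape[1]):
        raise TortuflowError(f"region box ({x0},{y0},{x1},{y1}) invalid for shape {shape}")
    m = np.zeros(shape, dtype=bool)
    m[x0:x1, y0:y1] = True
    return m


def default_noise_region(shape, corner: int | None = None) -> np.ndarray:
    """Four-corner air region used when no explicit noise ROI is supplied."""
    if corner is None:
        corner = max(4, min(shape) // 8)
    m = np.zeros(shape, dtype=bool)
    m[:corner, :corner] = m[:corner, -corner:] = True
    m[-corner:, :corner] = m[-corner:, -corner:] = True
    return m


def vessel_mask(pair: PhaseMagPair, roi=None, noise_region=None,
                noise_multiplier: float = 5.0) -> np.ndarray:
    """Pixels in the ROI with magnitude above noise_multiplier times the
    mean magnitude of the background noise region."""
    shape = pair.magnitude.shape
    noise_m = default_noise_region(shape) if noise_region is None else _region_mask(noise_region, shape)
    roi_m = ~noise_m if roi is None else _region_mask(roi, shape)
    if not roi_m.any() or not noise_m.any():
        raise DegenerateInputError("ROI and noise region must be non-empty")
    if np.logical_and(roi_m, noise_m).any():
        raise TortuflowError("ROI and noise region must be disjoint")
    noise_level = float(pair.magnitude[noise_m].mean())
    mask = roi_m & (pair.magnitude > noise_multiplier * noise_level)
    if not mask.any():
        raise NoVesselSignalError(
            f"no vessel signal: no ROI pixel exceeds {noise_multiplier} x background "
            f"noise level {noise_level:.3g}"
        )
    return mask


def phase_to_velocity(pair: PhaseMagPair) -> np.ndarray:
    """v = VENC * phase / pi, elementwise, in cm/s."""
    if np.abs(pair.phase).max() > math.pi + _PHASE_TOL:
        raise TortuflowError("phase values outside [-pi, pi]: convert scanner units upstream")
    return pair.venc * pair.phase / math.pi


def blood_flux(velocity: np.ndarray, mask: np.ndarray, pixel_size: float) -> float:
    """|sum of masked velocities| x pixel area, reported in ml/min.

    Signed sum then absolute value: through-plane unidirectional flow.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("empty vessel mask")
    pixel_area_cm2 = (pixel_size / 10.0) ** 2
    return abs(float(np.asarray(velocity)[mask].sum())) * pixel_area_cm2 * 60.0


def max_velocity(velocity: np.ndarray, mask: np.ndarray) -> float:
    """MaxV: maximum |v| over the vessel mask, cm/s."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("empty vessel mask")
    return float(np.abs(np.asarray(velocity)[mask]).max())


def quantify_flow(pair: PhaseMagPair, roi=None, noise_region=None,
                  noise_multiplier: float = 5.0,
                  phase_offset_correction: bool = False) -> FlowResult:
    """Vessel mask -> velocity map -> flux and MaxV for one artery."""
    mask = vessel_mask(pair, roi=roi, noise_region=noise_region,
                       noise_multiplier=noise_multiplier)
    v = phase_to_velocity(pair)
    if phase_offset_correction:
        # optional static-tissue offset subtraction; disabled by default
        noise_m = default_noise_region(pair.magnitude.shape) if noise_region is None \
            else _region_mask(noise_region, pair.magnitude.shape)
        v = v - float(v[noise_m].mean())
    return FlowResult(
        flux=blood_flux(v, mask, pair.pixel_size),
        max_velocity=max_velocity(v, mask),
        mask_pixel_count=int(mask.sum()),
    )


def unit_cbf(fluxes, brain_mass_g: float) -> float:
    """CBF = sum of the four arteries' fluxes / brain mass x 100, ml/min/100 g."""
    fluxes = [float(f) for f in fluxes]
    if len(fluxes) != 4:
        raise TortuflowError(f"unit CBF requires exactly 4 per-artery fluxes, got {len(fluxes)}")
    if any(f < 0 for f in fluxes):
        raise TortuflowError("fluxes must be non-negative")
    if brain_mass_g <= 0:
        raise TortuflowError("brain mass must be positive")
    return sum(fluxes) / brain_mass_g * 100.0


def cov_intersession(m1: float, m2: float, sqrt2_denominator: bool = True) -> float:
    """Scan-rescan coefficient of variation |m1 - m2| / (sqrt(2) * mean).

    The sqrt(2) denominator is the standard two-measurement within-subject
    CoV; set ``sqrt2_denominator=False`` for a plain 2 * mean denominator.
    """
    if m1 <= 0 or m2 <= 0:
        raise TortuflowError("CoV requires positive measurements")
    denom = (math.sqrt(2.0) if sqrt2_denominator else 2.0) * (m1 + m2) / 2.0
    return abs(m1 - m2) / denom
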