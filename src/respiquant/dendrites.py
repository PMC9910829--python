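"""Radial octant analysis of dendritic fluorescence.

A radial grid of eight 45-degree sectors is centred on the motor pool;
zero degrees is the ray running from the midline through the centre of
the cell bodies, i.e. pointing laterally, and angles increase
counterclockwise toward dorsal.  Fluorescence belonging to the cell
bodies themselves is deleted by masking a disc before profiling.  Each
octant's integrated intensity ("IntDen": the plain pixel sum) is divided
by the total unmasked intensity, giving eight fractions that sum to one.
Octants 0-90 degrees summarise dorsolateral dendrites; 180-225 plus
315-360 degrees summarise ventral dendrites.

For images of the left hemicord (cell-body centre left of the midline
column) the angular frame is mirrored automatically, so "lateral" is
always 0 degrees and "dorsal" always 90 degrees regardless of side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityImage",
    "RadialFrame",
    "OctantProfile",
    "mask_body",
    "octant_profile",
    "region_fractions",
]

N_OCTANTS = 8
OCTANT_DEG = 45.0


@dataclass(frozen=True)
class IntensityImage:
    """Single-channel fluorescence image with physical pixel size.

    ``midline_col_px`` locates the spinal cord midline; together with the
    cell-body centre it fixes the lateral (zero-degree) direction.  Row 0
    is dorsal (image up = dorsal).
    """

    pixels: np.ndarray
    um_per_px: float
    midline_col_px: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("image must be 2D single-channel")
        if np.any(px < 0):
            raise ValueError("intensities must be non-negative")
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be positive")


@dataclass(frozen=True)
class RadialFrame:
    """Centre of the cell-body cluster and the radius of the masked disc."""

    center_px: tuple[float, float]  # (row, col)
    body_radius_um: float = 0.0
    outer_radius_um: float | None = None  # None: full image extent

    def __post_init__(self) -> None:
        if self.body_radius_um < 0:
            raise ValueError("body_radius_um must be non-negative")


@dataclass(frozen=True)
class OctantProfile:
    """Eight angular intensity fractions; octant k covers [45k, 45(k+1)) degrees."""

    fractions: np.ndarray
    total_intensity: float
    dorsolateral_fraction: float
    ventral_fraction: float
    mirrored: bool = False  # True when a left-hemicord frame was flipped

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", f)
        if f.shape != (N_OCTANTS,):
            raise ValueError("profile must have eight fractions")


def _radial_coords(img: IntensityImage, frame: RadialFrame):
    """Per-pixel radius (um) and polar angle (deg, CCW-toward-dorsal from lateral)."""
    h, w = img.pixels.shape
    r0, c0 = frame.center_px
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("frame centre must lie inside the image")
    rows = np.arange(h)[:, None] - r0
    cols = np.arange(w)[None, :] - c0
    mirrored = c0 < img.midline_col_px
    lateral = -cols if mirrored else cols  # +lateral: away from the midline
    dorsal = -rows * np.ones_like(cols)  # +dorsal: up (decreasing row)
    radius_um = np.hypot(rows * np.ones_like(cols), cols * np.ones_like(rows)) * img.um_per_px
    angle_deg = np.degrees(np.arctan2(dorsal, lateral)) % 360.0
    return radius_um, angle_deg, mirrored


def mask_body(img: IntensityImage, frame: RadialFrame) -> IntensityImage:
    """Delete cell-body fluorescence: zero all pixels strictly inside the body disc.

    Pure operation (the input image is untouched); a pixel exactly at the
    radius is kept.
    """
    radius_um, _, _ = _radial_coords(img, frame)
    inside = radius_um < frame.body_radius_um
    if inside.all():
        logger.warning("body mask covers the entire image")
    out = img.pixels.copy()
    out[inside] = 0.0
    return IntensityImage(out, img.um_per_px, img.midline_col_px)


def octant_profile(img_masked: IntensityImage, frame: RadialFrame) -> OctantProfile:
    """Fraction of total fluorescence in each 45-degree octant about the centre.

    Pixels are assigned by the polar angle of their centre (half-open
    octants, boundary angles go to the higher octant); pixels beyond
    ``outer_radius_um`` (if set) are ignored.  Requires nonzero total
    intensity after masking.
    """
    radius_um, angle_deg, mirrored = _radial_coords(img_masked, frame)
    weights = img_masked.pixels
    keep = radius_um >= frame.body_radius_um
    if frame.outer_radius_um is not None:
        keep &= radius_um <= frame.outer_radius_um
    octant = np.minimum((angle_deg // OCTANT_DEG).astype(int), N_OCTANTS - 1)
    sums = np.bincount(octant[keep].ravel(), weights=weights[keep].ravel(), minlength=N_OCTANTS)
    total = float(sums.sum())
    if total <= 0:
        raise ValueError("zero total intensity outside the body mask")
    fractions = sums / total
    dl, vent = _region_fractions(fractions)
    return OctantProfile(
        fractions=fractions,
        total_intensity=total,
        dorsolateral_fraction=dl,
        ventral_fraction=vent,
        mirrored=mirrored,
    )


def _region_fractions(fractions: np.ndarray) -> tuple[float, float]:
    dorsolateral = float(fractions[0] + fractions[1])  # 0-45 + 45-90 degrees
    ventral = float(fractions[4] + fractions[7])  # 180-225 + 315-360 degrees
    return dorsolateral, ventral


def region_fractions(profile: OctantProfile) -> tuple[float, float]:
    """(dorsolateral, ventral) intensity fractions: 0-90 and 180-225 + 315-360 degrees."""
    return _region_fractions(profile.fractions)
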