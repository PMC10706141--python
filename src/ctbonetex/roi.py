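"""Trabecular ROI delineation on axial CT slices.

The trabecular compartment is isolated by HU-window thresholding; the
axial slice with the largest trabecular cross-section is selected; and a
circular region of interest is fitted inside the trabecular area, within
which all texture statistics are computed.  Everything here is
deterministic — ties are broken by lowest index, and the circle is a pure
function of the thresholded mask.

The default HU window [50, 400] brackets typical trabecular attenuation
between marrow fat/water (≈ −100…0 HU) and cortical bone (> 700 HU).
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import ndimage

from .containers import MIN_ROI_PIXELS, CTSlice, CTVolume, ROIMask
from .exceptions import ConfigurationError, NoTrabecularTissueError, ROITooSmallError

__all__ = [
    "DEFAULT_HU_WINDOW",
    "DEFAULT_SHRINK",
    "threshold_trabecular_mask",
    "select_largest_trabecular_slice",
    "fit_circular_roi",
    "circular_trabecular_roi",
]

DEFAULT_HU_WINDOW: Tuple[float, float] = (50.0, 400.0)
DEFAULT_SHRINK = 0.9



def threshold_trabecular_mask(
    slc: CTSlice,
    hu_low: float = DEFAULT_HU_WINDOW[0],
    hu_high: float = DEFAULT_HU_WINDOW[1],
) -> ROIMask:
    """Mask the pixels with ``hu_low <= HU <= hu_high``.

    Raises :class:`NoTrabecularTissueError` when nothing falls in the
    window, mirroring the cohort-exclusion rule for cases without a
    measurable trabecular section.
    """
    if hu_low >= hu_high:
        raise ConfigurationError("hu_low must be < hu_high")
    mask = (slc.hu >= hu_low) & (slc.hu <= hu_high)
    if not mask.any():
        raise NoTrabecularTissueError(
            f"no pixel in HU window [{hu_low}, {hu_high}]"
        )
    return ROIMask(mask=mask, circle=None)


def select_largest_trabecular_slice(
    volume: CTVolume,
    hu_low: float = DEFAULT_HU_WINDOW[0],
    hu_high: float = DEFAULT_HU_WINDOW[1],
) -> Tuple[int, CTSlice]:
    """Pick the slice maximizing in-window pixel count (ties: lowest index)."""
    if hu_low >= hu_high:
        raise ConfigurationError("hu_low must be < hu_high")
    counts = [
        int(((s.hu >= hu_low) & (s.hu <= hu_high)).sum()) for s in volume.slices
    ]
    if max(counts) == 0:
        raise NoTrabecularTissueError("all slices empty after thresholding")
    idx = int(np.argmax(counts))  # argmax returns the first maximum
    return idx, volume.slices[idx]


def _solidify(mask: np.ndarray) -> np.ndarray:
    """Convex hull of the strut mask — the trabecular territory.

    The thresholded mask is fragmented at the strut scale; the region the
    circle must inscribe is the territory the struts span, not the struts
    themselves, and the convex hull is its deterministic, parameter-free
    envelope.
    """
    from skimage.morphology import convex_hull_image

    return convex_hull_image(mask) | mask


def fit_circular_roi(mask: ROIMask, shrink: float = DEFAULT_SHRINK) -> ROIMask:
    """Fit a circle inside the trabecular mask and return the disk ROI.

    The circle is centred at the mask centroid with radius ``shrink``
    times the distance from the centroid to the nearest exterior point.
    The thresholded trabecular mask is fragmented at the strut scale, so
    the exterior is measured against its convex hull (the territory the
    struts span); the image border counts as exterior half a pixel
    beyond the outermost pixel centers.  ``shrink < 1`` keeps the disk
    clear of the cortical rim.

    The returned ROI holds every pixel strictly inside the circle.
    """
    if not 0 < shrink <= 1:
        raise ConfigurationError("shrink must be in (0, 1]")
    m = mask.mask
    if not m.any():
        raise ROITooSmallError("empty mask")
    nrow, ncol = m.shape
    rows, cols = np.nonzero(m)
    cr, cc = float(rows.mean()), float(cols.mean())

    solid = _solidify(m)
    exterior = ~solid
    if exterior.any():
        err, ecc = np.nonzero(exterior)
        d_ext = float(np.min(np.hypot(err - cr, ecc - cc)))
    else:
        d_ext = np.inf
    d_edge = min(cr + 0.5, cc + 0.5, nrow - 0.5 - cr, ncol - 0.5 - cc)
    radius = shrink * min(d_ext, d_edge)

    rr, ccg = np.mgrid[0:nrow, 0:ncol]
    disk = (rr - cr) ** 2 + (ccg - cc) ** 2 < radius**2
    if disk.sum() < MIN_ROI_PIXELS:
        raise ROITooSmallError(
            f"circular ROI holds {int(disk.sum())} px < {MIN_ROI_PIXELS}"
        )
    return ROIMask(mask=disk, circle=(cr, cc, radius))


def circular_trabecular_roi(
    slc: CTSlice,
    hu_low: float = DEFAULT_HU_WINDOW[0],
    hu_high: float = DEFAULT_HU_WINDOW[1],
    shrink: float = DEFAULT_SHRINK,
) -> ROIMask:
    """Threshold then fit the circular ROI — the per-slice composition."""
    return fit_circular_roi(threshold_trabecular_mask(slc, hu_low, hu_high), shrink)
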