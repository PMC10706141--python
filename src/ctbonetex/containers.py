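"""In-memory containers for CT images and regions of interest.

Hounsfield units are carried as float arrays throughout; signed storage
conventions (DICOM rescale slope/intercept, 16-bit PNG offsets) are the
business of :mod:`ctbonetex.io`, not of these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = ["CTSlice", "CTVolume", "ROIMask", "MIN_ROI_PIXELS"]

#: Minimum in-ROI pixel count for texture statistics to be meaningful.
MIN_ROI_PIXELS = 16


@dataclass(frozen=True)
class CTSlice:
    """A single axial CT image in Hounsfield units.

    Parameters
    ----------
    hu : ndarray of shape (rows, cols)
        Hounsfield-unit image; all values finite.
    spacing : (float, float)
        Pixel spacing in mm, (row, col).
    """

    hu: np.ndarray
    spacing: Tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu, dtype=float)
        if hu.ndim != 2:
            raise ValueError(f"slice must be 2-D, got shape {hu.shape}")
        if min(hu.shape) < 8:
            raise ValueError(f"slice must be at least 8x8, got {hu.shape}")
        if not np.all(np.isfinite(hu)):
            raise ValueError("slice contains non-finite HU values")
        object.__setattr__(self, "hu", hu)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.hu.shape


@dataclass(frozen=True)
class CTVolume:
    """An ordered stack of axial slices with common in-plane shape."""

    slices: Tuple[CTSlice, ...]
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        slices = tuple(self.slices)
        if not slices:
            raise ValueError("volume needs at least one slice")
        shape0 = slices[0].shape
        if any(s.shape != shape0 for s in slices):
            raise ValueError("all slices in a volume must share one shape")
        object.__setattr__(self, "slices", slices)

    def __len__(self) -> int:
        return len(self.slices)

    def __getitem__(self, i: int) -> CTSlice:
        return self.slices[i]

    def as_array(self) -> np.ndarray:
        """Stack HU images into a (n_slices, rows, cols) array."""
        return np.stack([s.hu for s in self.slices])


@dataclass(frozen=True)
class ROIMask:
    """Boolean region of interest over one slice.

    ``circle`` is ``(center_row, center_col, radius_px)`` when the mask was
    produced by circular fitting; in that case the mask holds exactly the
    pixels strictly inside the circle.  A thresholding mask carries no
    circle.
    """

    mask: np.ndarray
    circle: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "mask", mask)
        if self.circle is not None:
            object.__setattr__(self, "circle", tuple(float(v) for v in self.circle))

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def pixel_values(self, slc: CTSlice) -> np.ndarray:
        """Extract the in-ROI HU values of ``slc`` as a flat array."""
        if slc.shape != self.mask.shape:
            raise ValueError("mask and slice shapes differ")
        return slc.hu[self.mask]
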