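"""Typed errors for case exclusion and configuration problems.

Degenerate inputs (no trabecular tissue in the HU window, a region too
small to support texture statistics, under-determined regression designs)
are surfaced as distinct exception types so a cohort-level driver can log
the exclusion reason per case instead of silently skipping it.
"""


class CTBoneTexError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CTBoneTexError, ValueError):
    """Invalid user-supplied configuration (sizes, counts, windows, grids)."""


class NoTrabecularTissueError(CTBoneTexError):
    """Thresholding left no pixel inside the HU window — case excluded."""


class ROITooSmallError(CTBoneTexError):
    """Circular ROI holds fewer pixels than texture statistics require."""


class ROIFragmentedError(CTBoneTexError):
    """No valid in-ROI pixel pair exists at the co-occurrence offset."""


class UnderdeterminedError(CTBoneTexError):
    """Fewer samples than trainable parameters for a strict linear fit."""


class ConvergenceError(CTBoneTexError):
    """Iterative solver exhausted its budget; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
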