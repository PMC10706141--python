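"""Synthetic trabecular-bone CT cohorts with known ground truth.

No public cohort exists for opportunistic bone-density screening from
chest CT, so every downstream stage is exercised on simulated data in
which the quantities the pipeline estimates — bone mineral content (BMC,
g) and bone mineral density (BMD, g/cm²) — are planted by construction.

The texture model is a thresholded Gaussian-smoothed white-noise field, a
standard stochastic proxy for porous media: smoothing sets the trabecular
correlation length, and the threshold quantile sets the bone-voxel
fraction.  The bone fraction is a monotone function of the subject's true
BMC, so the mean ROI attenuation (and the co-occurrence texture around it)
carries a recoverable BMC signal.  Each subject is scanned at two
timepoints; the second scan reuses the first scan's latent field with a
small perturbation, emulating the strong within-subject correlation of
longitudinal CT.

What this generator does *not* emulate: vertebral/femoral anatomy,
cortical shells, scanner physics (beam hardening, reconstruction kernels)
or patient positioning.  See ``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .containers import CTSlice, CTVolume
from .exceptions import ConfigurationError
from .io import write_volume

__all__ = [
    "SimConfig",
    "SubjectRecord",
    "SyntheticCohort",
    "draw_ground_truth",
    "render_slice_stack",
    "generate_cohort",
    "write_cohort",
]

#: Correlation between the two timepoints' latent texture fields.
FIELD_PERSISTENCE = 0.98

#: Through-stack bone-area taper per slice of distance from the centre.
SLICE_TAPER = 0.15

#: Floor applied to timepoint-2 BMC after the longitudinal shift (g).
BMC_FLOOR = 0.5


@dataclass(frozen=True)
class SimConfig:
    """Cohort-simulation parameters.

    Defaults are plausibility choices for an L1 vertebral trabecular ROI:
    BMC around the mid-teens of grams, BMD near 1 g/cm², a BMC–BMD
    correlation near 0.9, and small (sub-gram) two-year BMC changes.
    """

    n_subjects: int = 50
    image_size: int = 64
    pixel_spacing: float = 0.7  # mm
    n_slices: int = 5
    hu_bone: float = 400.0
    hu_marrow: float = 0.0
    noise_sd: float = 20.0  # HU
    smoothing_sigma: float = 1.5  # px, trabecular correlation length
    bmc_mean: float = 15.0  # g
    bmc_sd: float = 3.0  # g
    bmd_mean: float = 1.0  # g/cm^2
    bmd_sd: float = 0.15  # g/cm^2
    bmc_bmd_corr: float = 0.9
    change_mean: float = -0.5  # g, timepoint-2 BMC shift
    change_sd: float = 0.5  # g
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.image_size < 16:
            raise ConfigurationError("image_size must be >= 16")
        if self.n_slices < 1:
            raise ConfigurationError("n_slices must be >= 1")
        if min(self.bmc_sd, self.bmd_sd, self.noise_sd) < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if abs(self.bmc_bmd_corr) > 1:
            raise ConfigurationError("|bmc_bmd_corr| must be <= 1")
        if self.smoothing_sigma <= 0:
            raise ConfigurationError("smoothing_sigma must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass(frozen=True)
class SubjectRecord:
    """One scan of one subject, with its planted DXA-style references."""

    subject_id: str
    timepoint: int  # 1 or 2
    volume: CTVolume
    bmc_true: float  # g
    bmd_true: float  # g/cm^2

    def __post_init__(self) -> None:
        if self.timepoint not in (1, 2):
            raise ValueError("timepoint must be 1 or 2")
        if self.bmc_true <= 0:
            raise ValueError("bmc_true must be positive")


@dataclass(frozen=True)
class SyntheticCohort:
    """All records of a simulated cohort plus the manifest of ground truth."""

    records: Tuple[SubjectRecord, ...]
    config: SimConfig
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if len(self.records) != 2 * self.config.n_subjects:
            raise ValueError("cohort must hold exactly two records per subject")
        if len(self.manifest) != len(self.records):
            raise ValueError("manifest must have one row per record")


def bone_fraction(bmc: np.ndarray | float, config: SimConfig) -> np.ndarray | float:
    """Monotone link from true BMC (g) to trabecular bone-voxel fraction.

    Linear around ``bmc_mean`` with slope chosen so ±3 SD of BMC spans the
    clip band [0.05, 0.95]; degenerate ``bmc_sd = 0`` falls back to a fixed
    0.05/g slope.
    """
    slope = 0.45 / (3.0 * config.bmc_sd) if config.bmc_sd > 0 else 0.05
    f = 0.5 + slope * (np.asarray(bmc, dtype=float) - config.bmc_mean)
    return np.clip(f, 0.05, 0.95)


def draw_ground_truth(
    config: SimConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw per-subject (BMC, BMD) from the configured bivariate normal.

    Returns two arrays of length ``n_subjects``; BMC values are floored at
    a small positive value so every record satisfies ``bmc_true > 0``.
    """
    r = config.bmc_bmd_corr
    cov = np.array(
        [
            [config.bmc_sd**2, r * config.bmc_sd * config.bmd_sd],
            [r * config.bmc_sd * config.bmd_sd, config.bmd_sd**2],
        ]
    )
    mean = np.array([config.bmc_mean, config.bmd_mean])
    draws = rng.multivariate_normal(mean, cov, size=config.n_subjects)
    bmc = np.maximum(draws[:, 0], BMC_FLOOR)
    bmd = np.maximum(draws[:, 1], 1e-3)
    return bmc, bmd


def _slice_profile(n_slices: int) -> np.ndarray:
    """Through-stack weights peaking at the central slice."""
    centre = (n_slices - 1) / 2.0
    idx = np.arange(n_slices)
    return np.maximum(1.0 - SLICE_TAPER * np.abs(idx - centre), 0.1)


def _latent_fields(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Smoothed white-noise fields, one per slice, unit-free."""
    raw = rng.standard_normal((config.n_slices, config.image_size, config.image_size))
    return np.stack([gaussian_filter(f, config.smoothing_sigma) for f in raw])


def _render_from_fields(
    fields: np.ndarray,
    frac: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> CTVolume:
    """Threshold latent fields at the per-slice bone-fraction quantile."""
    profile = _slice_profile(config.n_slices)
    slices: List[CTSlice] = []
    for field, weight in zip(fields, profile):
        f_slice = float(np.clip(frac * weight, 0.0, 1.0))
        if f_slice >= 1.0:
            bone = np.ones_like(field, dtype=bool)
        elif f_slice <= 0.0:
            bone = np.zeros_like(field, dtype=bool)
        else:
            # empirical quantile => the rendered fraction is exact
            thresh = np.quantile(field, 1.0 - f_slice)
            bone = field >= thresh
        hu = np.where(bone, config.hu_bone, config.hu_marrow).astype(float)
        if config.noise_sd > 0:
            hu = hu + rng.normal(0.0, config.noise_sd, size=hu.shape)
        spacing = (config.pixel_spacing, config.pixel_spacing)
        slices.append(CTSlice(hu=hu, spacing=spacing))
    spacing3 = (config.pixel_spacing, config.pixel_spacing, 5.0)
    return CTVolume(slices=tuple(slices), spacing=spacing3)


def render_slice_stack(
    bmc_true: float,
    config: SimConfig,
    rng: np.random.Generator,
    bone_fraction_override: Optional[float] = None,
) -> CTVolume:
    """Render one scan for a subject with the given true BMC.

    The bone-voxel fraction is ``bone_fraction(bmc_true)`` unless
    ``bone_fraction_override`` is given (useful for degenerate checks; the
    override bypasses the [0.05, 0.95] clip).  Bone area tapers away from
    the central slice so slice selection has a well-defined maximum.
    """
    if bmc_true <= 0:
        raise ConfigurationError("bmc_true must be positive")
    frac = (
        float(bone_fraction_override)
        if bone_fraction_override is not None
        else float(bone_fraction(bmc_true, config))
    )
    fields = _latent_fields(config, rng)
    return _render_from_fields(fields, frac, config, rng)


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Simulate the full two-timepoint cohort.

    Deterministic given ``config.seed``.  Per subject: draw (BMC, BMD)
    from the bivariate normal; timepoint-2 BMC adds a
    Normal(change_mean, change_sd) shift floored at a small positive
    value, and BMD shifts proportionally; the timepoint-2 texture reuses
    the timepoint-1 latent field with a small fresh perturbation.
    """
    rng = np.random.default_rng(config.seed)
    bmc1, bmd1 = draw_ground_truth(config, rng)
    change = rng.normal(config.change_mean, config.change_sd, size=config.n_subjects)
    bmc2 = np.maximum(bmc1 + change, BMC_FLOOR)
    # BMD tracks the relative BMC change (projected area is stable)
    bmd2 = np.maximum(bmd1 * (bmc2 / bmc1), 1e-3)

    records: List[SubjectRecord] = []
    rows = []
    width = len(str(config.n_subjects))
    for i in range(config.n_subjects):
        sid = f"S{i + 1:0{width}d}"
        fields1 = _latent_fields(config, rng)
        fresh = _latent_fields(config, rng)
        rho = FIELD_PERSISTENCE
        fields2 = rho * fields1 + np.sqrt(1.0 - rho**2) * fresh
        for tp, fields, bmc, bmd in (
            (1, fields1, float(bmc1[i]), float(bmd1[i])),
            (2, fields2, float(bmc2[i]), float(bmd2[i])),
        ):
            frac = float(bone_fraction(bmc, config))
            vol = _render_from_fields(fields, frac, config, rng)
            records.append(
                SubjectRecord(
                    subject_id=sid, timepoint=tp, volume=vol,
                    bmc_true=bmc, bmd_true=bmd,
                )
            )
            rows.append(
                {
                    "subject_id": sid,
                    "timepoint": tp,
                    "path": "",
                    "bmc_true": bmc,
                    "bmd_true": bmd,
                }
            )
    manifest = pd.DataFrame(rows)
    return SyntheticCohort(records=tuple(records), config=config, manifest=manifest)


def write_cohort(
    cohort: SyntheticCohort, directory: str | Path, fmt: str = "png"
) -> Path:
    """Write every scan to ``directory`` and return the manifest CSV path.

    ``fmt`` is one of ``png`` (16-bit PNG per slice + JSON sidecar),
    ``npy`` or ``dicom``.  The manifest CSV has columns subject_id,
    timepoint, path, bmc_true, bmd_true; paths are relative to the
    manifest so the directory is relocatable.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    paths = []
    for rec in cohort.records:
        rel = f"{rec.subject_id}_tp{rec.timepoint}"
        write_volume(rec.volume, directory / rel, fmt=fmt)
        paths.append(rel)
    manifest["path"] = paths
    manifest_path = directory / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    config_path = directory / "sim_config.json"
    config_path.write_text(json.dumps(cohort.config.to_dict(), indent=2, sort_keys=True))
    return manifest_path
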