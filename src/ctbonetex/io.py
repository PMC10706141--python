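"""Reading and writing CT slice stacks.

Three interchangeable on-disk layouts are supported, all carrying pixel
spacing and a signed-HU storage convention:

``png``
    One 16-bit grayscale PNG per slice plus one JSON sidecar.  PNG stores
    unsigned integers, so HU are shifted by a rescale intercept of −1024
    (the air floor of the Hounsfield scale), mirroring how CT DICOM stores
    pixel data: ``HU = stored × slope + intercept``.
``dicom``
    One minimal DICOM file per slice (Rows, Columns, PixelSpacing,
    RescaleSlope/RescaleIntercept, 16-bit pixel data), read back through
    pydicom with the same rescale equation.
``npy``
    A single ``.npy`` float array (n_slices, rows, cols) plus the JSON
    sidecar; lossless for arbitrary float HU.

The integer formats round HU to the nearest integer on write; integer-
valued HU in [−1024, 64511] round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import imageio.v3 as iio
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .containers import CTSlice, CTVolume

__all__ = ["write_volume", "read_volume"]

_INTERCEPT = -1024.0
_SLOPE = 1.0


def _sidecar(volume: CTVolume, fmt: str) -> dict:
    return {
        "format": fmt,
        "n_slices": len(volume),
        "spacing": list(volume.spacing),
        "rescale_slope": _SLOPE,
        "rescale_intercept": _INTERCEPT,
    }


def _encode(hu: np.ndarray) -> np.ndarray:
    stored = np.rint((hu - _INTERCEPT) / _SLOPE)
    if stored.min() < 0 or stored.max() > np.iinfo(np.uint16).max:
        raise ValueError("HU outside the representable 16-bit window")
    return stored.astype(np.uint16)


def _decode(stored: np.ndarray) -> np.ndarray:
    return stored.astype(float) * _SLOPE + _INTERCEPT


def write_volume(volume: CTVolume, base: str | Path, fmt: str = "png") -> Path:
    """Write ``volume`` under the path stem ``base``; returns the sidecar/dir.

    ``png``/``npy`` write ``<base>_s###.png`` / ``<base>.npy`` plus
    ``<base>.json``; ``dicom`` writes a ``<base>/`` directory of ``.dcm``
    files.
    """
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "png":
        for i, slc in enumerate(volume.slices):
            iio.imwrite(base.with_name(f"{base.name}_s{i:03d}.png"), _encode(slc.hu))
        side = base.with_suffix(".json")
        side.write_text(json.dumps(_sidecar(volume, "png"), indent=2, sort_keys=True))
        return side
    if fmt == "npy":
        np.save(base.with_suffix(".npy"), volume.as_array())
        side = base.with_suffix(".json")
        side.write_text(json.dumps(_sidecar(volume, "npy"), indent=2, sort_keys=True))
        return side
    if fmt == "dicom":
        outdir = base
        outdir.mkdir(parents=True, exist_ok=True)
        series_uid = generate_uid(entropy_srcs=[base.name])
        for i, slc in enumerate(volume.slices):
            _write_dicom_slice(slc, volume, i, series_uid, outdir / f"s{i:03d}.dcm")
        return outdir
    raise ValueError(f"unknown format {fmt!r}")


def _write_dicom_slice(
    slc: CTSlice, volume: CTVolume, index: int, series_uid: str, path: Path
) -> None:
    stored = _encode(slc.hu)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid(
        entropy_srcs=[path.parent.name, str(index)]
    )
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid
    ds.Modality = "CT"
    ds.InstanceNumber = index + 1
    ds.Rows, ds.Columns = stored.shape
    ds.PixelSpacing = [str(slc.spacing[0]), str(slc.spacing[1])]
    ds.SliceThickness = str(volume.spacing[2])
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0  # unsigned
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = str(_SLOPE)
    ds.RescaleIntercept = str(_INTERCEPT)
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_volume(base: str | Path) -> CTVolume:
    """Read a slice stack written by :func:`write_volume`.

    ``base`` is the path stem used at write time (for DICOM, the series
    directory; any directory containing ``.dcm`` files is accepted).
    """
    base = Path(base)
    if base.is_dir():
        return _read_dicom_dir(base)
    side = base.with_suffix(".json")
    if not side.exists():
        raise FileNotFoundError(f"no sidecar {side} and {base} is not a DICOM dir")
    meta = json.loads(side.read_text())
    spacing3 = tuple(float(v) for v in meta["spacing"])
    slope, intercept = float(meta["rescale_slope"]), float(meta["rescale_intercept"])
    spacing2 = spacing3[:2]
    if meta["format"] == "npy":
        arr = np.load(base.with_suffix(".npy"))
        slices = [CTSlice(hu=a, spacing=spacing2) for a in arr]
    else:
        slices = []
        for i in range(int(meta["n_slices"])):
            stored = iio.imread(base.with_name(f"{base.name}_s{i:03d}.png"))
            hu = stored.astype(float) * slope + intercept
            slices.append(CTSlice(hu=hu, spacing=spacing2))
    return CTVolume(slices=tuple(slices), spacing=spacing3)


def _read_dicom_dir(directory: Path) -> CTVolume:
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    slices = []
    thickness = 1.0
    for f in files:
        ds = pydicom.dcmread(f)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(float) * slope + intercept
        spacing = tuple(float(v) for v in getattr(ds, "PixelSpacing", [1.0, 1.0]))
        thickness = float(getattr(ds, "SliceThickness", 1.0))
        slices.append(CTSlice(hu=hu, spacing=spacing))
    sp = slices[0].spacing
    return CTVolume(slices=tuple(slices), spacing=(sp[0], sp[1], thickness))
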