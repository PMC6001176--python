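"""Readers for the slice containers the metric is run on.

Supported inputs: NIfTI-1 volumes (sliced along a chosen axis), DICOM
series directories (sorted by instance number, rescale slope/intercept
applied), and single-slice grayscale PNG/TIFF.  Intensities are passed
through unmodified — the metric performs its own standardization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pydicom

__all__ = ["SliceRecord", "load_slices"]

NIFTI_SUFFIXES = (".nii", ".nii.gz")
IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


@dataclass(frozen=True)
class SliceRecord:
    source_path: str
    slice_index: int
    image: np.ndarray


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in NIFTI_SUFFIXES)


def _load_nifti(path: Path, axis: int) -> list[SliceRecord]:
    vol = np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
    if vol.ndim == 2:
        return [SliceRecord(str(path), 0, vol)]
    if vol.ndim == 4 and vol.shape[-1] == 1:
        vol = vol[..., 0]
    if vol.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D or 3-D volume, got shape {vol.shape}")
    vol = np.moveaxis(vol, axis, 0)
    return [SliceRecord(str(path), i, vol[i]) for i in range(vol.shape[0])]


def _load_dicom_dir(path: Path) -> list[SliceRecord]:
    datasets = []
    for f in sorted(path.iterdir()):
        if f.is_file():
            try:
                datasets.append((f, pydicom.dcmread(str(f))))
            except Exception:
                continue  # non-DICOM clutter in the directory
    if not datasets:
        raise IOError(f"{path}: no readable DICOM files in directory")
    datasets.sort(key=lambda fd: int(getattr(fd[1], "InstanceNumber", 0)))
    records = []
    for i, (f, ds) in enumerate(datasets):
        arr = ds.pixel_array.astype(np.float64)
        if arr.ndim != 2:
            raise ValueError(f"{f}: expected a 2-D grayscale frame, got {arr.shape}")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        records.append(SliceRecord(str(f), i, arr * slope + intercept))
    return records


def _load_image(path: Path) -> list[SliceRecord]:
    arr = np.asarray(iio.imread(str(path)))
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: RGB/multichannel images are not supported")
    return [SliceRecord(str(path), 0, arr.astype(np.float64))]


def load_slices(path: str | Path, axis: int = -1) -> list[SliceRecord]:
    """Extract 2-D grayscale slices from a file or DICOM directory.

    ``axis`` selects the slicing axis for NIfTI volumes (default: last).
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"no such file or directory: {p}")
    if p.is_dir():
        return _load_dicom_dir(p)
    if _is_nifti(p):
        return _load_nifti(p, axis)
    if p.suffix.lower() in IMAGE_SUFFIXES:
        return _load_image(p)
    raise ValueError(f"{p}: unrecognized input format (expect NIfTI, DICOM dir, PNG/TIFF)")
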