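"""NIfTI and CSV input/output.

The on-disk standard is NIfTI-1: 4D volumes for dynamic series (4th
dimension = time), 3D volumes for masks and label maps.  Tables (PSIC
curves, descriptors, reports) are plain CSV via pandas.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .preprocess import DynamicSeries

__all__ = [
    "FormatError",
    "read_series",
    "write_series",
    "read_mask",
    "write_mask",
    "read_label_map",
    "write_label_map",
]


class FormatError(ValueError):
    """Raised for files that are not the expected NIfTI shape or content."""


def _load(path: str | Path) -> nib.Nifti1Image:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    return img


def read_series(path: str | Path, frame_interval: float = 83.0) -> DynamicSeries:
    """Read a 4D dynamic series (x, y, z, time)."""
    img = _load(path)
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise FormatError(
            f"{path}: expected a 4D dynamic series, got {data.ndim}D data"
        )
    return DynamicSeries(data=data, frame_interval=frame_interval, affine=img.affine)


def write_series(series: DynamicSeries, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(series.data, series.affine), str(path))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 3D binary mask; non-binary volumes are rejected."""
    img = _load(path)
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D mask, got {data.ndim}D data")
    if not np.isin(data, (0.0, 1.0)).all():
        raise FormatError(f"{path}: mask contains values other than 0 and 1")
    return data.astype(bool)


def write_mask(mask: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))


def read_label_map(path: str | Path) -> np.ndarray:
    """Read a 3D integer label map (e.g. cluster assignments)."""
    img = _load(path)
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D label map, got {data.ndim}D data")
    if not np.allclose(data, np.round(data)):
        raise FormatError(f"{path}: label map contains non-integer values")
    return data.astype(np.int32)


def write_label_map(
    labels: np.ndarray, path: str | Path, affine: np.ndarray | None = None
) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int32), affine), str(path))
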