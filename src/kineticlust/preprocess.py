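"""Preprocessing of dynamic series: relative enhancement and difference images.

Raw gray-level time courses ``S(tau)`` depend on scanner gain and protocol;
dividing out the precontrast frame yields the relative-enhancement course
``x(tau) = (S(tau) - S(1)) / S(1)`` which is invariant to global intensity
rescaling and is the feature vector used everywhere downstream.  Frames are
stored 0-based in memory; the clinical convention ("k-th postcontrast frame")
maps to array index ``k``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DynamicSeries",
    "EnhancementSeries",
    "InsufficientFramesError",
    "to_relative_enhancement",
    "difference_image",
]


class InsufficientFramesError(ValueError):
    """Raised when an operation needs more dynamic frames than are present."""


def _default_affine() -> np.ndarray:
    return np.eye(4)


@dataclass
class DynamicSeries:
    """A 4D dynamic acquisition.

    ``data`` is indexed ``(x, y, z, tau)`` with ``tau = 0`` the precontrast
    frame.  ``frame_interval`` (seconds) is carried as metadata only; the
    standard protocol acquires 6 frames 83 s apart.
    """

    data: np.ndarray
    frame_interval: float = 83.0
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("dynamic series data must be 4D (x, y, z, time)")
        if self.data.shape[-1] < 3:
            raise InsufficientFramesError("a dynamic series needs at least 3 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("series intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class EnhancementSeries:
    """Per-voxel relative-enhancement time courses.

    ``data[..., 0]`` is 0 at every valid voxel; voxels whose precontrast
    signal did not exceed the floor are marked invalid and carry all-zero
    courses that must be excluded from downstream statistics via
    ``valid_mask``.
    """

    data: np.ndarray
    valid_mask: np.ndarray

    def vectors(self, mask: np.ndarray) -> np.ndarray:
        """Enhancement curves of the voxels selected by a 3D boolean mask,
        as an ``(n_voxels, n_frames)`` matrix in C voxel order."""
        return self.data[np.asarray(mask, bool)]


def to_relative_enhancement(
    series: DynamicSeries, precontrast_floor: float = 1.0
) -> EnhancementSeries:
    """Convert raw intensities to relative enhancement.

    ``x(tau) = (S(tau) - S(0)) / S(0)`` wherever the precontrast signal
    exceeds ``precontrast_floor`` (default 1 intensity unit, which keeps air
    voxels from blowing up the division); other voxels are flagged invalid.
    Issues a warning (not an error) if no voxel is valid.
    """
    s0 = series.data[..., 0]
    valid = s0 > precontrast_floor
    x = np.zeros_like(series.data)
    np.divide(
        series.data - s0[..., None],
        s0[..., None],
        out=x,
        where=valid[..., None],
    )
    if not valid.any():
        warnings.warn(
            "no voxel exceeds the precontrast floor; enhancement series is empty",
            stacklevel=2,
        )
    return EnhancementSeries(data=x, valid_mask=valid)


def difference_image(series: DynamicSeries) -> np.ndarray:
    """Subtraction image: third postcontrast frame minus precontrast frame.

    The strongest, most reliable lesion contrast in the standard protocol is
    around the third postcontrast acquisition, so this image is used to
    localize enhancing lesions (and to auto-place region-growing seeds).
    """
    if series.n_frames < 4:
        raise InsufficientFramesError("difference image needs at least 4 frames")
    return series.data[..., 3] - series.data[..., 0]
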