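"""Threshold segmentation, seeded region growing, and the conventional
ROI-average analysis.

The clinical-standard ("conventional") reading of an enhancing lesion:
threshold the per-voxel initial-enhancement map at 50 %, grow the connected
component around a manually (or automatically) placed seed, average the raw
signal curves of the resulting ROI, and rate that single mean curve.  The
averaging step is exactly what the clustering method later improves on — a
small washout subpopulation disappears into the ROI mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .curves import CurveDescriptors, KuhlClass, classify_curve, curve_descriptors
from .preprocess import DynamicSeries, to_relative_enhancement

__all__ = [
    "LesionROI",
    "ConventionalResult",
    "SeedOutsideLesionError",
    "EmptyROIError",
    "sai_map",
    "threshold_mask",
    "region_grow",
    "conventional_analysis",
]

#: Sentinel written into the sa_i map at invalid voxels; compares below any
#: finite threshold.
SAI_SENTINEL = -np.inf


class SeedOutsideLesionError(ValueError):
    """Raised when no above-threshold voxel lies within snapping range of the seed."""


class EmptyROIError(ValueError):
    """Raised when an analysis is requested on an empty ROI."""


@dataclass
class LesionROI:
    """A segmented lesion: one connected component of the threshold mask.

    ``connectivity`` is 6 (face neighbors) or 26 (face+edge+corner) in 3D.
    """

    mask: np.ndarray
    seed: tuple[int, int, int]
    connectivity: int = 26

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ConventionalResult:
    """Outcome of the conventional ROI-average analysis."""

    mean_curve: np.ndarray
    descriptors: CurveDescriptors
    kuhl_class: KuhlClass
    score: int


def sai_map(series: DynamicSeries, precontrast_floor: float = 1.0) -> np.ndarray:
    """Voxelwise initial contrast enhancement (percent).

    Invalid voxels (precontrast signal at or below the floor) receive
    ``-inf`` so that any finite threshold excludes them.
    """
    enh = to_relative_enhancement(series, precontrast_floor)
    sai = np.where(enh.valid_mask, 100.0 * enh.data[..., 2], SAI_SENTINEL)
    return sai


def threshold_mask(sai: np.ndarray, threshold: float = 50.0) -> np.ndarray:
    """Voxels whose initial enhancement meets the threshold (inclusive)."""
    return np.asarray(sai) >= threshold


def _structure(connectivity: int, two_d: bool = False) -> np.ndarray:
    if connectivity == 6:
        st = ndimage.generate_binary_structure(3, 1)
    elif connectivity == 26:
        st = ndimage.generate_binary_structure(3, 3)
    else:
        raise ValueError("connectivity must be 6 or 26")
    if two_d:  # no growth across slices (z axis is last)
        st = st.copy()
        st[:, :, 0] = False
        st[:, :, 2] = False
    return st


def region_grow(
    mask: np.ndarray,
    seed: Sequence[int],
    connectivity: int = 26,
    snap_radius: float = 2.0,
    two_d: bool = False,
) -> LesionROI:
    """Connected component of ``mask`` containing (or nearest to) the seed.

    Seeds come from an approximate manual click or the difference-image
    maximum, so a seed that misses the mask is snapped to the nearest masked
    voxel within ``snap_radius`` (Euclidean, default 2 voxels); beyond that
    a :class:`SeedOutsideLesionError` is raised.  With ``two_d`` the region
    grows within axial slices only.
    """
    mask = np.asarray(mask, dtype=bool)
    seed = tuple(int(c) for c in seed)
    if len(seed) != 3 or any(c < 0 or c >= g for c, g in zip(seed, mask.shape)):
        raise ValueError(f"seed {seed} lies outside the grid {mask.shape}")
    if not mask[seed]:
        seed = _snap_seed(mask, seed, snap_radius)
    labels, _ = ndimage.label(mask, structure=_structure(connectivity, two_d))
    component = labels == labels[seed]
    return LesionROI(mask=component, seed=seed, connectivity=connectivity)


def _snap_seed(
    mask: np.ndarray, seed: tuple[int, int, int], snap_radius: float
) -> tuple[int, int, int]:
    candidates = np.argwhere(mask)
    if candidates.size == 0:
        raise SeedOutsideLesionError("mask is empty; nothing to segment")
    d2 = ((candidates - np.asarray(seed)) ** 2).sum(axis=1)
    best = np.lexsort((candidates[:, 2], candidates[:, 1], candidates[:, 0], d2))[0]
    if d2[best] > snap_radius**2:
        raise SeedOutsideLesionError(
            f"no above-threshold voxel within {snap_radius} voxels of seed {seed}"
        )
    return tuple(int(c) for c in candidates[best])


def conventional_analysis(
    series: DynamicSeries,
    roi: LesionROI,
    plateau_band: float = 10.0,
    linearity_min: float = 0.98,
) -> ConventionalResult:
    """ROI-average rating of a lesion.

    Averages the raw signal-intensity curves over the ROI, computes sa_i and
    sv_p on the mean curve, and assigns a single Kuhl class (and ordinal
    score) to the whole lesion.
    """
    if roi.voxel_count == 0:
        raise EmptyROIError("conventional analysis requires a nonempty ROI")
    mean_curve = series.data[roi.mask].mean(axis=0)
    descr = curve_descriptors(mean_curve)
    cls = classify_curve(mean_curve, plateau_band, linearity_min)
    return ConventionalResult(
        mean_curve=mean_curve, descriptors=descr, kuhl_class=cls, score=cls.score
    )
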