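"""Threshold segmentation, region growing, conventional ROI analysis."""

from collections import deque
from itertools import product

import numpy as np
import pytest

from kineticlust import (
    DynamicSeries,
    KineticModel,
    KuhlClass,
    Lesion,
    PhantomSpec,
    conventional_analysis,
    generate_phantom,
    region_grow,
    sai_map,
    threshold_mask,
)
from kineticlust.segment import EmptyROIError, SeedOutsideLesionError


def flood_fill(mask: np.ndarray, seed, connectivity: int) -> np.ndarray:
    """Independent breadth-first flood fill used as the region-growing oracle."""
    offsets = [
        o
        for o in product((-1, 0, 1), repeat=3)
        if o != (0, 0, 0) and (connectivity == 26 or sum(map(abs, o)) == 1)
    ]
    out = np.zeros_like(mask, dtype=bool)
    if not mask[seed]:
        return out
    out[seed] = True
    queue = deque([seed])
    while queue:
        v = queue.popleft()
        for o in offsets:
            nb = tuple(v[i] + o[i] for i in range(3))
            if all(0 <= nb[i] < mask.shape[i] for i in range(3)):
                if mask[nb] and not out[nb]:
                    out[nb] = True
                    queue.append(nb)
    return out


def _phantom_series(noise=0.0, amplitude=0.8, seed=0):
    spec = PhantomSpec(
        grid=(12, 12, 9),
        lesions=(
            Lesion.homogeneous(
                (5, 5, 4), 2.5, KineticModel(KuhlClass.II, amplitude=amplitude)
            ),
        ),
        noise_sigma=noise,
        seed=seed,
    )
    data, truth = generate_phantom(spec)
    return DynamicSeries(np.clip(data, 0, None)), truth


class TestSaiMap:
    def test_zero_noise_phantom_values(self):
        series, truth = _phantom_series()
        sai = sai_map(series)
        assert np.allclose(sai[truth.lesion_mask(0)], 80.0)
        assert np.allclose(sai[~truth.lesion_mask(0)], 0.0)

    def test_invalid_voxel_gets_sentinel_below_any_threshold(self):
        arr = np.ones((2, 1, 1, 6)) * 100
        arr[0, 0, 0, 0] = 0.0  # dead precontrast voxel
        sai = sai_map(DynamicSeries(arr))
        assert sai[0, 0, 0] == -np.inf
        assert not threshold_mask(sai, -1e30)[0, 0, 0]


class TestThresholdMask:
    def test_threshold_is_inclusive(self):
        sai = np.array([[[50.0, 49.999], [50.001, 0.0]]])
        mask = threshold_mask(sai, 50.0)
        assert mask.tolist() == [[[True, False], [True, False]]]

    def test_toy_slice_count(self):
        sai = np.array([[[60.0], [40.0], [0.0]], [[55.0], [70.0], [10.0]], [[0.0], [0.0], [0.0]]])
        assert threshold_mask(sai, 50).sum() == 3

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        sai = rng.uniform(0, 100, size=(6, 6, 4))
        for lo, hi in [(10, 30), (30, 60), (59.9, 60.1)]:
            m_hi = threshold_mask(sai, hi)
            m_lo = threshold_mask(sai, lo)
            assert not np.any(m_hi & ~m_lo)


class TestRegionGrow:
    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_bfs_flood_fill_on_random_masks(self, connectivity):
        rng = np.random.default_rng(5)
        for _ in range(25):
            mask = rng.random((12, 12, 12)) < 0.35
            seeds = np.argwhere(mask)
            if len(seeds) == 0:
                continue
            seed = tuple(seeds[rng.integers(len(seeds))])
            roi = region_grow(mask, seed, connectivity=connectivity)
            assert np.array_equal(roi.mask, flood_fill(mask, seed, connectivity))

    def test_disjoint_blobs_isolated(self):
        mask = np.zeros((10, 10, 3), dtype=bool)
        mask[1:3, 1:3, 1] = True
        mask[7:9, 7:9, 1] = True
        roi = region_grow(mask, (1, 1, 1))
        assert roi.voxel_count == 4
        assert not roi.mask[7, 7, 1]

    def test_seed_snapping_within_radius(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[4, 4, 4] = True
        roi = region_grow(mask, (4, 4, 2), snap_radius=2.0)
        assert roi.seed == (4, 4, 4)
        with pytest.raises(SeedOutsideLesionError):
            region_grow(mask, (4, 4, 1), snap_radius=2.0)

    def test_empty_mask_raises(self):
        with pytest.raises(SeedOutsideLesionError):
            region_grow(np.zeros((5, 5, 5), dtype=bool), (2, 2, 2))

    def test_idempotent_from_any_member_voxel(self):
        rng = np.random.default_rng(11)
        mask = rng.random((10, 10, 10)) < 0.4
        seeds = np.argwhere(mask)
        seed = tuple(seeds[0])
        roi = region_grow(mask, seed)
        for v in np.argwhere(roi.mask)[::7]:
            again = region_grow(mask, tuple(v))
            assert np.array_equal(again.mask, roi.mask)

    def test_two_d_mode_stays_in_slice(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = True
        mask[1, 1, 2] = True
        roi = region_grow(mask, (1, 1, 1), two_d=True)
        assert roi.voxel_count == 1


class TestConventionalAnalysis:
    def test_homogeneous_washout_lesion_scores_4(self):
        spec = PhantomSpec(
            grid=(12, 12, 9),
            lesions=(
                Lesion.homogeneous(
                    (5, 5, 4),
                    2.5,
                    KineticModel(KuhlClass.III, amplitude=0.7, washout_fraction=-0.35),
                ),
            ),
        )
        data, _ = generate_phantom(spec)
        series = DynamicSeries(data)
        roi = region_grow(threshold_mask(sai_map(series)), (5, 5, 4))
        result = conventional_analysis(series, roi)
        assert result.kuhl_class is KuhlClass.III
        assert result.score == 4

    def test_single_voxel_roi_mean_is_that_voxel(self):
        series, truth = _phantom_series()
        mask = np.zeros_like(truth.lesion_mask(0))
        voxel = tuple(np.argwhere(truth.lesion_mask(0))[0])
        mask[voxel] = True
        from kineticlust.segment import LesionROI

        result = conventional_analysis(series, LesionROI(mask=mask, seed=voxel))
        assert np.array_equal(result.mean_curve, series.data[voxel])

    def test_empty_roi_rejected(self):
        series, _ = _phantom_series()
        from kineticlust.segment import LesionROI

        empty = LesionROI(mask=np.zeros(series.grid, dtype=bool), seed=(0, 0, 0))
        with pytest.raises(EmptyROIError):
            conventional_analysis(series, empty)

    def test_mixture_lesion_cluster_score_at_least_conventional(self):
        """A benign-dominant lesion with a washout core: the ROI mean can read
        as steady/plateau while clustering isolates the washout prototype."""
        from kineticlust import score_lesion

        washout = KineticModel(KuhlClass.III, amplitude=0.7, washout_fraction=-0.4)
        steady = KineticModel(KuhlClass.Ia, amplitude=1.0)
        lesion = Lesion((5, 5, 4), 2.5, ((washout, 0.2), (steady, 0.8)))
        spec = PhantomSpec(grid=(12, 12, 9), lesions=(lesion,))
        data, _ = generate_phantom(spec)
        series = DynamicSeries(data)
        conv, clust = score_lesion(series, random_state=0)
        assert clust == 4
        assert clust >= conv
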