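"""Vector-quantization engines: single steps, training, assignment, limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from kineticlust import (
    MinimalFreeEnergyVQ,
    NeuralGasVQ,
    TrainingSchedule,
    assign,
    distortion,
    mfe_step,
    neighborhood_rank,
    neural_gas_step,
    train,
)
from kineticlust.cluster import make_estimator, mfe_cooperativity

from conftest import noisy_four_population_roi


class TestNeighborhoodRank:
    def test_single_prototype(self):
        assert neighborhood_rank([0.5], [[1.0]]).tolist() == [0]

    def test_hand_example(self):
        ranks = neighborhood_rank([0.9], [[0.0], [1.0], [3.0]])
        assert ranks.tolist() == [1, 0, 2]

    def test_tie_broken_by_lower_index(self):
        ranks = neighborhood_rank([0.5], [[0.0], [1.0]])
        assert ranks.tolist() == [0, 1]

    @given(
        n=st.integers(1, 8),
        d=st.integers(1, 5),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=100, derandomize=True)
    def test_always_a_permutation(self, n, d, seed):
        rng = np.random.default_rng(seed)
        ranks = neighborhood_rank(rng.normal(size=d), rng.normal(size=(n, d)))
        assert sorted(ranks.tolist()) == list(range(n))


class TestNeuralGasStep:
    def test_hand_example_exact(self):
        w = neural_gas_step([0.25], [[0.0], [1.0]], alpha=0.5, lam=1.0)
        assert w[0, 0] == pytest.approx(0.125, abs=1e-12)
        assert w[1, 0] == pytest.approx(1 - 0.375 * math.exp(-1), abs=1e-12)

    def test_no_motion_when_prototypes_at_datum(self):
        cb = np.array([[0.3, 0.7], [0.3, 0.7]])
        w = neural_gas_step([0.3, 0.7], cb, alpha=0.9, lam=2.0)
        assert np.array_equal(w, cb)

    def test_small_lambda_limit_is_winner_only_kmeans_update(self):
        rng = np.random.default_rng(1)
        cb = rng.normal(size=(5, 4))
        x = rng.normal(size=4)
        w = neural_gas_step(x, cb, alpha=0.4, lam=1e-9)
        winner = int(np.argmin(np.linalg.norm(cb - x, axis=1)))
        expected = cb.copy()
        expected[winner] += 0.4 * (x - expected[winner])
        assert np.allclose(w, expected, atol=1e-9)

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=60, derandomize=True)
    def test_update_stays_in_bounding_box(self, seed):
        rng = np.random.default_rng(seed)
        cb = rng.uniform(-1, 1, size=(4, 3))
        x = rng.uniform(-1, 1, size=3)
        w = neural_gas_step(x, cb, alpha=rng.uniform(0, 1), lam=rng.uniform(0.01, 5))
        lo = np.minimum(cb, x).min(axis=0)
        hi = np.maximum(cb, x).max(axis=0)
        assert np.all(w >= lo - 1e-12) and np.all(w <= hi + 1e-12)


class TestMFEStep:
    def test_hand_example_exact(self):
        a = mfe_cooperativity([0.0], [[0.0], [1.0]], rho=1.0)
        z = 1.0 / (1.0 + math.exp(-0.5))
        assert a[0] == pytest.approx(z, abs=1e-12)
        assert a[1] == pytest.approx(1 - z, abs=1e-12)
        w = mfe_step([0.0], [[0.0], [1.0]], epsilon=0.5, rho=1.0)
        assert w[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert w[1, 0] == pytest.approx(1 - 0.5 * (1 - z), abs=1e-12)

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=100, derandomize=True)
    def test_cooperativities_normalized(self, seed):
        rng = np.random.default_rng(seed)
        a = mfe_cooperativity(
            rng.normal(size=3),
            rng.normal(size=(rng.integers(1, 7), 3)),
            rho=float(rng.uniform(0.05, 5)),
        )
        assert abs(a.sum() - 1.0) < 1e-12
        assert np.all((a >= 0) & (a <= 1))

    def test_large_rho_limit_uniform(self):
        rng = np.random.default_rng(2)
        a = mfe_cooperativity(rng.normal(size=4), rng.normal(size=(6, 4)), rho=1e6)
        assert np.allclose(a, 1 / 6, atol=1e-6)

    def test_softmax_shift_invariance_and_stability(self):
        # huge distances must not underflow to nan thanks to max-subtraction
        cb = np.array([[1e4], [1e4 + 1.0]])
        a = mfe_cooperativity([0.0], cb, rho=1.0)
        assert np.all(np.isfinite(a)) and abs(a.sum() - 1.0) < 1e-12
        assert a[0] > a[1]


class TestTraining:
    def test_exact_cover_reaches_zero_distortion(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        data = np.repeat(pts, 10, axis=0)
        schedule = TrainingSchedule(epochs=30)
        for method in ("neural_gas", "mfe"):
            cb = train(data, 4, method=method, schedule=schedule, random_state=0)
            assert distortion(data, cb) < 1e-6

    def test_two_gaussian_clouds_recovered(self):
        means = np.array([[-3.0], [3.0]])
        for seed in range(10):
            rng = np.random.default_rng(seed)
            data = np.vstack(
                [rng.normal(m, 0.5, size=(100, 1)) for m in means]
            )
            cb = train(data, 2, random_state=seed)
            got = np.sort(cb.ravel())
            se = 0.5 / np.sqrt(100)
            assert np.all(np.abs(got - means.ravel()) < 3 * se + 0.05)

    def test_training_reduces_distortion_from_initialization(self):
        rng = np.random.default_rng(0)
        data = np.vstack(
            [rng.normal(m, 0.3, size=(60, 3)) for m in (-2, 0, 2)]
        )
        for seed in range(20):
            est = NeuralGasVQ(n_clusters=3, random_state=seed).fit(data)
            init = est._init_codebook(data, np.random.default_rng(seed))
            assert est.distortion_ <= distortion(data, init) + 1e-12

    def test_seeded_determinism_bitwise(self):
        data = np.random.default_rng(3).normal(size=(50, 6))
        for method in ("neural_gas", "mfe"):
            a = train(data, 3, method=method, random_state=99)
            b = train(data, 3, method=method, random_state=99)
            assert np.array_equal(a, b)

    def test_n_clusters_must_not_exceed_data(self):
        with pytest.raises(ValueError):
            train(np.zeros((3, 2)), 4)

    def test_zero_noise_partition_recovery_both_methods(self, four_population_roi):
        X, truth = four_population_roi
        for method in ("neural_gas", "mfe"):
            for seed in (0, 7, 13):
                est = make_estimator(4, method, None, seed).fit(X)
                assert adjusted_rand_score(truth, est.labels_) == 1.0

    def test_noisy_partition_recovery(self):
        X, truth = noisy_four_population_roi(3)
        est = NeuralGasVQ(n_clusters=4, random_state=3).fit(X)
        assert adjusted_rand_score(truth, est.labels_) > 0.9


class TestAssignmentAndDistortion:
    def test_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            data = rng.normal(size=(rng.integers(1, 40), 4))
            cb = rng.normal(size=(rng.integers(1, 6), 4))
            res = assign(data, cb)
            d2 = ((data[:, None, :] - cb[None, :, :]) ** 2).sum(axis=2)
            expected = np.array([int(np.flatnonzero(r == r.min())[0]) for r in d2])
            assert np.array_equal(res.labels, expected)
            assert distortion(data, cb) == pytest.approx(
                float(np.mean(d2.min(axis=1))), rel=1e-12
            )

    def test_datum_on_prototype_and_tie_to_lowest_index(self):
        cb = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 0.0]])
        res = assign(np.array([[1.0, 0.0], [0.5, 0.0]]), cb)
        assert res.labels.tolist() == [0, 0]

    def test_single_prototype_all_same_label(self):
        res = assign(np.random.default_rng(0).normal(size=(20, 3)), [[0.0, 0.0, 0.0]])
        assert np.all(res.labels == 0)

    def test_data_subset_of_codebook_zero_distortion(self):
        cb = np.array([[0.0, 1.0], [2.0, 3.0]])
        assert distortion(cb.copy(), cb) == 0.0
        assert distortion(np.array([[0.0, 4.0]]), [[0.0, 1.0]]) == pytest.approx(9.0)


class TestEstimatorInterface:
    def test_clone_and_get_params_roundtrip(self):
        est = NeuralGasVQ(n_clusters=3, alpha_init=0.5, random_state=1)
        params = est.get_params()
        assert params["alpha_init"] == 0.5
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_predict_matches_labels_and_transform_shape(self, four_population_roi):
        X, _ = four_population_roi
        for cls in (NeuralGasVQ, MinimalFreeEnergyVQ):
            est = cls(n_clusters=4, random_state=0).fit(X)
            assert np.array_equal(est.predict(X), est.labels_)
            assert est.transform(X).shape == (len(X), 4)
            assert est.cluster_centers_.shape == (4, 6)
            assert est.distortion_ >= 0

    def test_fit_predict_api(self, four_population_roi):
        X, truth = four_population_roi
        labels = NeuralGasVQ(n_clusters=4, random_state=0).fit_predict(X)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            TrainingSchedule(alpha_init=1.5)
        with pytest.raises(ValueError):
            TrainingSchedule(epochs=0)
        with pytest.raises(ValueError):
            NeuralGasVQ(n_clusters=2, lambda_init=-1.0).fit(np.zeros((5, 2)))
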