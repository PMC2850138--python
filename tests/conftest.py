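"""Shared fixtures: the canonical four-population lesion data used across
clustering, stability and acceptance tests."""

import logging

import numpy as np
import pytest

from kineticlust import KuhlClass, generate_curve
from kineticlust.phantom import reference_models


@pytest.fixture(autouse=True)
def _quiet_psic_warnings(caplog):
    # empty-cluster warnings are expected noise in multi-run experiments
    logging.getLogger("kineticlust.curves").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def population_curves() -> dict[KuhlClass, np.ndarray]:
    """Noise-free signal curves of the four reference kinetic populations."""
    return {cls: generate_curve(m, 6) for cls, m in reference_models().items()}


@pytest.fixture(scope="session")
def four_population_roi(population_curves):
    """Zero-noise ROI: 30 identical voxels per population, as relative
    enhancement vectors, plus the generating partition."""
    X = np.vstack(
        [np.tile((c - c[0]) / c[0], (30, 1)) for c in population_curves.values()]
    )
    truth = np.repeat(np.arange(4), 30)
    return X, truth


def noisy_four_population_roi(seed: int, sigma: float = 5.0):
    """Noisy variant: raw-signal noise of standard deviation ``sigma`` on a
    baseline of 100, then converted to relative enhancement."""
    models = reference_models()
    S = np.vstack([np.tile(generate_curve(m, 6), (30, 1)) for m in models.values()])
    S = S + np.random.default_rng(1000 + seed).normal(0.0, sigma, S.shape)
    truth = np.repeat(np.arange(4), 30)
    return (S - S[:, :1]) / S[:, :1], truth
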