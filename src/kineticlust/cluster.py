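"""Online vector quantization of voxel time courses.

Two competitive-learning engines partition the relative-enhancement curves of
an ROI into ``N`` prototypical time courses (codebook vectors):

* the **neural-gas network**, whose update strength for each prototype decays
  exponentially with its distance *rank* to the presented vector,

  ``w_i <- w_i + alpha * exp(-k_i / lambda) * (x - w_i)``,

  where ``k_i`` in ``0..N-1`` is the neighborhood rank; and

* **minimal-free-energy vector quantization** (deterministic-annealing soft
  clustering), whose update strength is the softmax cooperativity

  ``a_i = exp(-||x - w_i||^2 / 2 rho^2) / sum_j exp(-||x - w_j||^2 / 2 rho^2)``,
  ``w_i <- w_i + epsilon * a_i * (x - w_i)``,

  with the length scale ``rho`` annealed toward zero.

Both reduce to the online k-means winner-take-all update in the small
``lambda`` / small ``rho`` limit.  Training visits the data in seeded random
order for a fixed number of epochs while the step size and the cooperativity
range decay exponentially from their initial to their final values; with a
fixed seed the result is bit-reproducible.

The engines are exposed as scikit-learn style estimators
(:class:`NeuralGasVQ`, :class:`MinimalFreeEnergyVQ`) plus a thin functional
surface (:func:`train`, :func:`assign`, :func:`distortion`, and the single
update steps) for scripting and testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "TrainingSchedule",
    "ClusterAssignment",
    "NeuralGasVQ",
    "MinimalFreeEnergyVQ",
    "neighborhood_rank",
    "neural_gas_step",
    "mfe_cooperativity",
    "mfe_step",
    "train",
    "assign",
    "distortion",
    "make_estimator",
]


# ---------------------------------------------------------------------------
# single update steps (pure functions; the estimators call these)
# ---------------------------------------------------------------------------

def neighborhood_rank(x: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    """Distance ranks ``k_i`` of the prototypes for a data vector.

    ``k_i`` is the position of prototype ``i`` when all prototypes are sorted
    by increasing Euclidean distance to ``x``; ties are broken by prototype
    index (lower index gets the lower rank).  The result is always a
    permutation of ``0..N-1``.
    """
    codebook = np.atleast_2d(np.asarray(codebook, dtype=float))
    d = np.linalg.norm(codebook - np.asarray(x, dtype=float), axis=1)
    order = np.argsort(d, kind="stable")
    ranks = np.empty(len(d), dtype=np.intp)
    ranks[order] = np.arange(len(d))
    return ranks


def neural_gas_step(
    x: np.ndarray, codebook: np.ndarray, alpha: float, lam: float
) -> np.ndarray:
    """One neural-gas update; returns the new codebook.

    All prototypes move toward ``x`` simultaneously, attenuated by
    ``exp(-k_i / lambda)`` with ranks taken on the pre-update codebook.
    """
    codebook = np.atleast_2d(np.asarray(codebook, dtype=float))
    k = neighborhood_rank(x, codebook)
    h = alpha * np.exp(-k / lam)
    return codebook + h[:, None] * (np.asarray(x, dtype=float) - codebook)


def mfe_cooperativity(x: np.ndarray, codebook: np.ndarray, rho: float) -> np.ndarray:
    """Softmax activations ``a_i`` of the minimal-free-energy model.

    Evaluated with max-subtraction so that the normalization never underflows
    even when all squared distances are huge relative to ``rho``.
    """
    codebook = np.atleast_2d(np.asarray(codebook, dtype=float))
    d2 = np.sum((codebook - np.asarray(x, dtype=float)) ** 2, axis=1)
    z = -d2 / (2.0 * rho * rho)
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def mfe_step(
    x: np.ndarray, codebook: np.ndarray, epsilon: float, rho: float
) -> np.ndarray:
    """One minimal-free-energy update; returns the new codebook."""
    codebook = np.atleast_2d(np.asarray(codebook, dtype=float))
    a = mfe_cooperativity(x, codebook, rho)
    return codebook + epsilon * a[:, None] * (np.asarray(x, dtype=float) - codebook)


# ---------------------------------------------------------------------------
# schedules and assignment containers
# ---------------------------------------------------------------------------

@dataclass
class TrainingSchedule:
    """Annealing schedule shared by both engines.

    Every parameter decays exponentially from its initial to its final value
    over the total step count (epochs x data size).  ``None`` finals resolve
    to the conventional defaults: ``alpha_final = 0.01 * alpha_init``,
    ``lambda_init = N/4`` and ``lambda_final = 0.01`` for the neural gas,
    and for MFE ``epsilon_final = 0.1 * epsilon_init`` and ``rho_init`` set
    from the data scale (RMS distance to the data mean) with
    ``rho_final = 0.1 * rho_init``.
    """

    alpha_init: float = 0.3
    alpha_final: float | None = None
    lambda_init: float | None = None
    lambda_final: float = 0.01
    epsilon_init: float = 0.3
    epsilon_final: float | None = None
    rho_init: float | None = None
    rho_final: float | None = None
    epochs: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_init <= 1.0 and 0.0 <= self.epsilon_init <= 1.0):
            raise ValueError("step sizes must lie in [0, 1]")
        if self.alpha_final is not None and not (0.0 <= self.alpha_final <= self.alpha_init):
            raise ValueError("alpha_final must lie in [0, alpha_init]")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")


@dataclass(frozen=True)
class ClusterAssignment:
    """Hard assignment of data vectors to prototypes.

    ``labels[mu]`` is the index of the nearest prototype (Euclidean, ties to
    the lowest index); ``distances[mu]`` the distance to it.
    """

    labels: np.ndarray
    distances: np.ndarray


def _geom(p0: float, p1: float, frac: float) -> float:
    """Exponential interpolation p0 -> p1 at progress frac in [0, 1]."""
    return p0 * (p1 / p0) ** frac


def _nearest(data: np.ndarray, codebook: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d2 = ((data[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)  # argmin takes the first minimum: lowest index
    return labels, np.sqrt(d2[np.arange(len(data)), labels])


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class _OnlineVQ(TransformerMixin, ClusterMixin, BaseEstimator):
    """Shared online training loop of both vector quantizers."""

    def __init__(self, n_clusters=4, epochs=10, random_state=None):
        self.n_clusters = n_clusters
        self.epochs = epochs
        self.random_state = random_state

    # subclasses provide the annealed parameters and the update
    def _resolve_schedule(self, X: np.ndarray) -> tuple:
        raise NotImplementedError

    def _update(self, x: np.ndarray, W: np.ndarray, sched: tuple, frac: float) -> np.ndarray:
        raise NotImplementedError

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a nonempty 2D array (n_samples, n_frames)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        if self.n_clusters < 1 or self.n_clusters > X.shape[0]:
            raise ValueError(
                f"n_clusters={self.n_clusters} must lie in 1..n_samples={X.shape[0]}"
            )
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        return X

    def _init_codebook(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        # sample N distinct data vectors: prefer unique rows so that exactly-
        # repeated curves (e.g. noise-free phantoms) cannot seed duplicate
        # prototypes; fall back to row sampling when uniques run short
        unique = np.unique(X, axis=0)
        if len(unique) >= self.n_clusters:
            idx = rng.choice(len(unique), size=self.n_clusters, replace=False)
            return unique[np.sort(idx)].copy()
        idx = rng.choice(len(X), size=self.n_clusters, replace=False)
        return X[np.sort(idx)].copy()

    def fit(self, X, y=None):
        X = self._validate(X)
        rng = np.random.default_rng(self.random_state)
        W = self._init_codebook(X, rng)
        sched = self._resolve_schedule(X)
        total = self.epochs * len(X)
        t = 0
        for _ in range(self.epochs):
            for mu in rng.permutation(len(X)):
                frac = t / (total - 1) if total > 1 else 1.0
                W = self._update(X[mu], W, sched, frac)
                t += 1
        self.cluster_centers_ = W
        self.labels_, d = _nearest(X, W)
        self.distortion_ = float(np.mean(d**2))
        self.n_iter_ = total
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        """Nearest-prototype labels (Euclidean, ties to the lowest index)."""
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=float)
        labels, _ = _nearest(X, self.cluster_centers_)
        return labels

    def transform(self, X):
        """Distances from each sample to every prototype."""
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=float)
        return np.linalg.norm(
            X[:, None, :] - self.cluster_centers_[None, :, :], axis=2
        )


class NeuralGasVQ(_OnlineVQ):
    """Neural-gas vector quantizer.

    Parameters
    ----------
    n_clusters : int
        Number of codebook vectors ``N``.
    alpha_init, alpha_final : float
        Step size, annealed exponentially; ``alpha_final=None`` resolves to
        ``0.01 * alpha_init``.  The reference operating point for lesion
        curves is ``alpha_init=0.3`` over 10 epochs.
    lambda_init, lambda_final : float
        Rank-decay constant; ``lambda_init=None`` resolves to ``N/4`` (the
        reference operating point), ``lambda_final`` defaults to 0.01 so the
        late phase is effectively winner-take-all.
    epochs : int
        Passes over the data.
    random_state : int, Generator or None
        Seeds codebook initialization and the per-epoch data order.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters, n_frames)
        Final codebook (prototype time courses).
    labels_ : ndarray
        Nearest-prototype label of each training vector.
    distortion_ : float
        Mean squared distance of the training data to their winners.
    """

    def __init__(
        self,
        n_clusters=4,
        alpha_init=0.3,
        alpha_final=None,
        lambda_init=None,
        lambda_final=0.01,
        epochs=10,
        random_state=None,
    ):
        super().__init__(n_clusters=n_clusters, epochs=epochs, random_state=random_state)
        self.alpha_init = alpha_init
        self.alpha_final = alpha_final
        self.lambda_init = lambda_init
        self.lambda_final = lambda_final

    def _resolve_schedule(self, X):
        a0 = self.alpha_init
        a1 = self.alpha_final if self.alpha_final is not None else 0.01 * a0
        l0 = self.lambda_init if self.lambda_init is not None else self.n_clusters / 4.0
        l1 = self.lambda_final
        if not 0.0 <= a0 <= 1.0:
            raise ValueError("alpha_init must lie in [0, 1]")
        if l0 <= 0 or l1 <= 0 or l1 > l0:
            raise ValueError("decay constants must satisfy 0 < lambda_final <= lambda_init")
        return (a0, a1, l0, l1)

    def _update(self, x, W, sched, frac):
        a0, a1, l0, l1 = sched
        return neural_gas_step(x, W, _geom(a0, a1, frac), _geom(l0, l1, frac))


class MinimalFreeEnergyVQ(_OnlineVQ):
    """Minimal-free-energy (deterministic-annealing) vector quantizer.

    Parameters
    ----------
    n_clusters : int
        Number of codebook vectors.
    epsilon_init, epsilon_final : float
        Step size, annealed exponentially (``None`` final resolves to
        ``0.1 * epsilon_init``).  The decay is milder than the neural-gas
        step size on purpose: in deterministic annealing the cooling is
        carried by ``rho``, and the prototypes must stay mobile enough to
        separate when the softmax sharpens late in training.
    rho_init, rho_final : float
        "Fuzzy range" of the softmax cooperativity, annealed downward.
        ``rho_init=None`` resolves to the RMS distance of the training data
        to their mean (a natural data length scale); ``rho_final=None`` to
        ``0.1 * rho_init``.
    epochs, random_state
        As in :class:`NeuralGasVQ`.
    """

    def __init__(
        self,
        n_clusters=4,
        epsilon_init=0.3,
        epsilon_final=None,
        rho_init=None,
        rho_final=None,
        epochs=10,
        random_state=None,
    ):
        super().__init__(n_clusters=n_clusters, epochs=epochs, random_state=random_state)
        self.epsilon_init = epsilon_init
        self.epsilon_final = epsilon_final
        self.rho_init = rho_init
        self.rho_final = rho_final

    def _resolve_schedule(self, X):
        e0 = self.epsilon_init
        e1 = self.epsilon_final if self.epsilon_final is not None else 0.1 * e0
        if self.rho_init is not None:
            r0 = self.rho_init
        else:
            r0 = float(np.sqrt(np.mean(np.sum((X - X.mean(axis=0)) ** 2, axis=1))))
            r0 = max(r0, 1e-12)  # degenerate all-identical data
        r1 = self.rho_final if self.rho_final is not None else 0.1 * r0
        if not 0.0 <= e0 <= 1.0:
            raise ValueError("epsilon_init must lie in [0, 1]")
        if r0 <= 0 or r1 <= 0 or r1 > r0:
            raise ValueError("fuzzy ranges must satisfy 0 < rho_final <= rho_init")
        return (e0, e1, r0, r1)

    def _update(self, x, W, sched, frac):
        e0, e1, r0, r1 = sched
        return mfe_step(x, W, _geom(e0, e1, frac), _geom(r0, r1, frac))


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

Method = Literal["neural_gas", "mfe"]


def make_estimator(
    n_clusters: int,
    method: Method = "neural_gas",
    schedule: TrainingSchedule | None = None,
    random_state=None,
) -> _OnlineVQ:
    """Instantiate the estimator for a method name and schedule."""
    s = schedule or TrainingSchedule()
    if method == "neural_gas":
        return NeuralGasVQ(
            n_clusters=n_clusters,
            alpha_init=s.alpha_init,
            alpha_final=s.alpha_final,
            lambda_init=s.lambda_init,
            lambda_final=s.lambda_final,
            epochs=s.epochs,
            random_state=random_state,
        )
    if method == "mfe":
        return MinimalFreeEnergyVQ(
            n_clusters=n_clusters,
            epsilon_init=s.epsilon_init,
            epsilon_final=s.epsilon_final,
            rho_init=s.rho_init,
            rho_final=s.rho_final,
            epochs=s.epochs,
            random_state=random_state,
        )
    raise ValueError(f"unknown method {method!r}")


def train(
    data: np.ndarray,
    n_clusters: int,
    method: Method = "neural_gas",
    schedule: TrainingSchedule | None = None,
    random_state=None,
) -> np.ndarray:
    """Train a codebook on a set of feature vectors; returns the prototypes."""
    est = make_estimator(n_clusters, method, schedule, random_state)
    est.fit(np.asarray(data, dtype=float))
    return est.cluster_centers_


def assign(data: np.ndarray, codebook: np.ndarray) -> ClusterAssignment:
    """Label each vector with its nearest prototype."""
    codebook = np.atleast_2d(np.asarray(codebook, dtype=float))
    if codebook.shape[0] < 1:
        raise ValueError("codebook must contain at least one prototype")
    labels, d = _nearest(np.asarray(data, dtype=float), codebook)
    return ClusterAssignment(labels=labels, distances=d)


def distortion(data: np.ndarray, codebook: np.ndarray) -> float:
    """Mean squared Euclidean distance to the winning prototypes."""
    return float(np.mean(assign(data, codebook).distances ** 2))
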