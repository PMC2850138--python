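"""Kinetic-curve descriptors and Kuhl time-signal-intensity classes.

The diagnostic reading of a dynamic contrast-enhanced breast MRI voxel (or
cluster prototype) rests on two numbers computed from its signal-intensity
time course:

* ``sa_i`` — the *initial* contrast enhancement, the percent signal rise from
  the precontrast frame to the second postcontrast frame.
* ``sv_p`` — the *postinitial* signal course, the percent change from the
  early-postcontrast maximum (first or second postcontrast frame) to the last
  frame.  Negative values indicate washout.

Curves are then binned into the Kuhl taxonomy: type I is a steadily rising
course (Ia straight, Ib curved/saturating), type II a plateau, type III a
washout.  Types II and III are the malignant-type shapes.

Frame convention: curves are stored 0-based, with index 0 the precontrast
frame, so "k-th postcontrast frame" is index ``k``.  All descriptor formulas
below follow that convention.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "KuhlClass",
    "CurveDescriptors",
    "PSICCurve",
    "InvalidCurveError",
    "compute_sai",
    "compute_svp",
    "linearity",
    "curve_descriptors",
    "classify_kuhl",
    "classify_curve",
    "classify_psic",
    "psic_curves",
    "lesion_score",
]


class InvalidCurveError(ValueError):
    """Raised when a time course violates the preconditions of a descriptor."""


class KuhlClass(enum.Enum):
    """Kuhl time-signal-intensity curve type.

    The ordinal ``score`` (Ia=1, Ib=2, II=3, III=4) is the value used for
    lesion rating and ROC analysis; types II and III are malignant-type.
    """

    Ia = "Ia"
    Ib = "Ib"
    II = "II"
    III = "III"

    @property
    def score(self) -> int:
        return _SCORES[self]

    @property
    def malignant(self) -> bool:
        return self.score >= 3


_SCORES = {KuhlClass.Ia: 1, KuhlClass.Ib: 2, KuhlClass.II: 3, KuhlClass.III: 4}


@dataclass(frozen=True)
class CurveDescriptors:
    """Scalar descriptors of a signal-intensity time course.

    Attributes
    ----------
    sa_i : float
        Initial contrast enhancement in percent.
    sv_p : float
        Postinitial signal change in percent (negative = washout).
    linearity : float
        Coefficient of determination (R^2) of a straight-line fit to the
        postcontrast portion of the curve; used to split type I into
        Ia (straight) and Ib (curved).
    """

    sa_i: float
    sv_p: float
    linearity: float


@dataclass(frozen=True)
class PSICCurve:
    """Mean percentage signal-intensity-change curve of one cluster.

    ``values`` holds the framewise mean of ``100 * x(tau)`` over the member
    voxels, where ``x`` is relative enhancement; ``values[0]`` is 0 by
    construction (precontrast reference).
    """

    values: np.ndarray
    cluster_id: int
    member_count: int


def _as_curve(curve: Sequence[float]) -> np.ndarray:
    c = np.asarray(curve, dtype=float)
    if c.ndim != 1 or c.size < 3:
        raise InvalidCurveError("a time course needs at least 3 frames")
    if not np.all(np.isfinite(c)):
        raise InvalidCurveError("time course contains non-finite values")
    return c


def compute_sai(curve: Sequence[float]) -> float:
    """Initial contrast enhancement in percent.

    ``(SI[2nd postcontrast] - SI[pre]) / SI[pre] * 100``, i.e. frames 2 and 0
    of the 0-based curve.
    """
    c = _as_curve(curve)
    if c[0] <= 0:
        raise InvalidCurveError("precontrast signal must be positive")
    return float((c[2] - c[0]) / c[0] * 100.0)


def compute_svp(curve: Sequence[float]) -> float:
    """Postinitial signal course in percent.

    ``(SI[last] - M) / M * 100`` with ``M`` the maximum of the first and
    second postcontrast frames.  For the standard 6-frame protocol the last
    frame is the 5th postcontrast frame.
    """
    c = _as_curve(curve)
    m = max(c[1], c[2])
    if m <= 0:
        raise InvalidCurveError("early postcontrast maximum must be positive")
    return float((c[-1] - m) / m * 100.0)


def linearity(curve: Sequence[float]) -> float:
    """R^2 of a least-squares line through the postcontrast frames.

    A constant postcontrast course is perfectly fit by a flat line and
    returns 1.0.
    """
    c = _as_curve(curve)
    post = c[1:]
    if np.allclose(post, post[0], rtol=0.0, atol=1e-12 * max(1.0, abs(float(post[0])))):
        return 1.0
    res = stats.linregress(np.arange(post.size, dtype=float), post)
    return float(res.rvalue**2)


def curve_descriptors(curve: Sequence[float]) -> CurveDescriptors:
    """Compute :class:`CurveDescriptors` for a raw signal-intensity curve."""
    return CurveDescriptors(
        sa_i=compute_sai(curve),
        sv_p=compute_svp(curve),
        linearity=linearity(curve),
    )


def classify_kuhl(
    descr: CurveDescriptors,
    plateau_band: float = 10.0,
    linearity_min: float = 0.98,
) -> KuhlClass:
    """Assign a Kuhl class from curve descriptors.

    Washout (III) if ``sv_p < -plateau_band``; plateau (II) if
    ``|sv_p| <= plateau_band``; otherwise steady rise (type I), subdivided
    into Ia when the postcontrast course is straight
    (``linearity >= linearity_min``) and Ib when it is curved.

    The band defaults to +/-10 percent, the conventional reading of the
    Kuhl taxonomy; both thresholds are configuration-exposed because the
    class boundaries are a radiological convention, not a measured quantity.
    """
    if not (np.isfinite(descr.sv_p) and np.isfinite(descr.linearity)):
        raise InvalidCurveError("descriptors must be finite")
    if descr.sv_p < -plateau_band:
        return KuhlClass.III
    if descr.sv_p <= plateau_band:
        return KuhlClass.II
    if descr.linearity >= linearity_min:
        return KuhlClass.Ia
    return KuhlClass.Ib


def classify_curve(
    curve: Sequence[float],
    plateau_band: float = 10.0,
    linearity_min: float = 0.98,
) -> KuhlClass:
    """Classify a raw signal-intensity time course."""
    return classify_kuhl(curve_descriptors(curve), plateau_band, linearity_min)


def classify_psic(
    values: Sequence[float],
    plateau_band: float = 10.0,
    linearity_min: float = 0.98,
) -> KuhlClass:
    """Classify a PSIC (percent enhancement) curve.

    The percent curve is mapped back to a relative signal-intensity curve
    ``1 + values/100`` before applying the descriptors; since sa_i and sv_p
    are scale-invariant this is exact and baseline-free.
    """
    si = 1.0 + np.asarray(values, dtype=float) / 100.0
    return classify_curve(si, plateau_band, linearity_min)


def psic_curves(
    roi_enhancement: np.ndarray,
    labels: Sequence[int],
    n_clusters: int,
) -> list[PSICCurve]:
    """Per-cluster mean percentage signal-intensity-change curves.

    Parameters
    ----------
    roi_enhancement : ndarray, shape (n_voxels, n_frames)
        Relative-enhancement time courses ``x(tau)`` (fractional, frame 0
        equal to 0) of the ROI voxels.
    labels : sequence of int
        Cluster index in ``0..n_clusters-1`` per voxel.
    n_clusters : int
        Number of codebook vectors used in the clustering.

    Returns
    -------
    list of PSICCurve
        One entry per *nonempty* cluster, in cluster-index order.  Empty
        clusters are dropped with a logged warning: an empty prototype has
        no member curve to average.
    """
    x = np.asarray(roi_enhancement, dtype=float)
    lab = np.asarray(labels, dtype=int)
    if x.ndim != 2 or lab.shape != (x.shape[0],):
        raise ValueError("roi_enhancement must be (n_voxels, n_frames) matching labels")
    if lab.size and (lab.min() < 0 or lab.max() >= n_clusters):
        raise ValueError("labels must lie in 0..n_clusters-1")
    out: list[PSICCurve] = []
    for i in range(n_clusters):
        members = lab == i
        count = int(members.sum())
        if count == 0:
            logger.warning("cluster %d is empty and was dropped from the PSIC set", i)
            continue
        out.append(
            PSICCurve(
                values=100.0 * x[members].mean(axis=0),
                cluster_id=i,
                member_count=count,
            )
        )
    return out


def lesion_score(classes: Iterable[KuhlClass]) -> int:
    """Lesion-level rating: the highest class score among cluster prototypes.

    The most suspicious prototype determines the lesion, so a small washout
    subpopulation is not averaged away by surrounding benign-type voxels.
    """
    scores = [c.score for c in classes]
    if not scores:
        raise ValueError("lesion_score requires at least one classified cluster")
    return max(scores)
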