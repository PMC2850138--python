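"""Synthetic 4D DCE-MRI phantom with known per-voxel kinetics.

The phantom emulates a dynamic breast MRI study: a 3D grid imaged over
``n_frames`` time points (default 6: one precontrast, five postcontrast at a
nominal 83 s interval), containing non-enhancing background tissue and
compact spherical lesions whose voxels follow parametric Kuhl-type kinetic
curves plus additive noise.  Every voxel's generating curve and every
lesion's malignancy label are known exactly, so each downstream stage
(preprocessing, segmentation, clustering, classification, ROC analysis) can
be validated without patient data.

Curve parameterization (design choice; the clinical taxonomy is only drawn
schematically):

* frame 0 is the precontrast ``baseline``;
* frame 1 reaches ``baseline * (1 + amplitude * initial_fraction)`` with
  ``initial_fraction`` defaulting to 0.5 for types Ia/Ib and 1.0 for II/III;
* the remaining frames rise linearly to the peak (Ia), rise along a
  saturating exponential (Ib), stay at the plateau (II), or decline linearly
  from the peak to ``peak * (1 + washout_fraction)`` at the last frame (III).

Lesions may be kinetically heterogeneous: a lesion can carry several
components with fractional volumes, assigned to voxels concentrically
(innermost voxels to the first component).  The assignment is deterministic,
so changing the noise seed changes only the noise realization, never the
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .curves import KuhlClass

__all__ = [
    "KineticModel",
    "Lesion",
    "PhantomSpec",
    "GroundTruth",
    "InvalidModelError",
    "PhantomSpecError",
    "generate_curve",
    "generate_phantom",
    "reference_models",
    "spec_from_dict",
]

#: Default fraction of the full amplitude reached at the first postcontrast
#: frame, per Kuhl class. Steady-rise types reach half their amplitude early;
#: plateau/washout types peak immediately.
DEFAULT_INITIAL_FRACTION: Mapping[KuhlClass, float] = {
    KuhlClass.Ia: 0.5,
    KuhlClass.Ib: 0.5,
    KuhlClass.II: 1.0,
    KuhlClass.III: 1.0,
}


class InvalidModelError(ValueError):
    """Raised for kinetic models that violate their parameter constraints."""


class PhantomSpecError(ValueError):
    """Raised for phantom specifications that cannot be realized."""


@dataclass(frozen=True)
class KineticModel:
    """Parametric kinetic model of one voxel population.

    Parameters
    ----------
    kuhl_class : KuhlClass
        Curve shape family (Ia straight rise, Ib saturating rise, II plateau,
        III washout).
    amplitude : float
        Peak fractional enhancement (unitless; 0.8 means an 80 % rise over
        baseline).  Must be >= 0.
    baseline : float
        Precontrast signal intensity in arbitrary units; must be > 0.
    washout_fraction : float
        Signed fractional change from the peak to the last frame; negative
        only for class III (e.g. -0.25 = 25 % signal loss after the peak).
    initial_fraction : float, optional
        Fraction of the amplitude reached at the first postcontrast frame;
        defaults per class (0.5 for Ia/Ib, 1.0 for II/III).
    curvature : float
        Saturation rate of the type-Ib exponential rise (larger = more
        strongly curved); ignored for the other classes.
    """

    kuhl_class: KuhlClass
    amplitude: float
    baseline: float = 100.0
    washout_fraction: float = 0.0
    initial_fraction: float | None = None
    curvature: float = 3.0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise InvalidModelError("baseline must be positive")
        if self.amplitude < 0:
            raise InvalidModelError("amplitude must be non-negative")
        if self.washout_fraction < 0 and self.kuhl_class is not KuhlClass.III:
            raise InvalidModelError("negative washout_fraction is only valid for class III")
        if self.washout_fraction < -1:
            raise InvalidModelError("washout_fraction below -1 would drive the signal negative")
        f = self.initial_fraction
        if f is not None and not (0.0 < f <= 1.0):
            raise InvalidModelError("initial_fraction must lie in (0, 1]")
        if self.curvature <= 0:
            raise InvalidModelError("curvature must be positive")

    @property
    def resolved_initial_fraction(self) -> float:
        if self.initial_fraction is not None:
            return self.initial_fraction
        return DEFAULT_INITIAL_FRACTION[self.kuhl_class]


def generate_curve(model: KineticModel, n_frames: int = 6) -> np.ndarray:
    """Evaluate a kinetic model on the acquisition grid.

    Returns a length-``n_frames`` signal-intensity curve with ``curve[0]``
    equal to the baseline.  Requires ``n_frames >= 3`` (precontrast, at least
    one early postcontrast frame, and a last frame).
    """
    if n_frames < 3:
        raise ValueError("n_frames must be at least 3")
    b = model.baseline
    peak = b * (1.0 + model.amplitude)
    early = b * (1.0 + model.amplitude * model.resolved_initial_fraction)
    # u runs 0..1 over the postcontrast frames
    u = np.arange(n_frames - 1, dtype=float) / (n_frames - 2)
    curve = np.empty(n_frames, dtype=float)
    curve[0] = b
    cls = model.kuhl_class
    if cls is KuhlClass.Ia:
        curve[1:] = early + (peak - early) * u
    elif cls is KuhlClass.Ib:
        k = model.curvature
        s = -np.expm1(-k * u) / -np.expm1(-k)
        curve[1:] = early + (peak - early) * s
    elif cls is KuhlClass.II:
        curve[1:] = early  # plateau held at the early enhancement level
    else:  # III: linear decline from the immediate peak
        last = peak * (1.0 + model.washout_fraction)
        curve[1:] = peak + (last - peak) * u
    return curve


@dataclass(frozen=True)
class Lesion:
    """A compact digital-sphere lesion.

    ``components`` lists ``(model, fraction)`` pairs whose fractions sum to 1;
    a homogeneous lesion has a single component.  Components are laid out
    concentrically in listing order (first component innermost).
    """

    center: tuple[int, int, int]
    radius: float
    components: tuple[tuple[KineticModel, float], ...]

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise PhantomSpecError("lesion radius must be at least 1 voxel")
        if not self.components:
            raise PhantomSpecError("lesion needs at least one kinetic component")
        fractions = np.array([f for _, f in self.components], dtype=float)
        if np.any(fractions <= 0) or abs(fractions.sum() - 1.0) > 1e-9:
            raise PhantomSpecError("component fractions must be positive and sum to 1")

    @classmethod
    def homogeneous(
        cls, center: Sequence[int], radius: float, model: KineticModel
    ) -> "Lesion":
        return cls(tuple(int(c) for c in center), float(radius), ((model, 1.0),))

    @property
    def kuhl_class(self) -> KuhlClass:
        """Most suspicious component class (the lesion-level ground truth)."""
        return max((m.kuhl_class for m, _ in self.components), key=lambda c: c.score)

    @property
    def malignant(self) -> bool:
        return self.kuhl_class.malignant


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic dynamic series."""

    grid: tuple[int, int, int]
    lesions: tuple[Lesion, ...]
    n_frames: int = 6
    background: KineticModel = field(
        default_factory=lambda: KineticModel(KuhlClass.Ia, amplitude=0.0, baseline=100.0)
    )
    noise_sigma: float = 0.0
    rician: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid) != 3 or any(g < 1 for g in self.grid):
            raise PhantomSpecError("grid must be three positive extents")
        if self.n_frames < 3:
            raise PhantomSpecError("n_frames must be at least 3")
        if self.noise_sigma < 0:
            raise PhantomSpecError("noise_sigma must be non-negative")
        for les in self.lesions:
            for dim, (c, g) in enumerate(zip(les.center, self.grid)):
                if c - les.radius < 0 or c + les.radius > g - 1:
                    raise PhantomSpecError(
                        f"lesion at {les.center} (radius {les.radius}) exceeds the grid "
                        f"along axis {dim}"
                    )


@dataclass(frozen=True)
class GroundTruth:
    """Per-voxel and per-lesion truth of a generated phantom.

    ``label_map`` holds 0 for background and ``k+1`` for lesion ``k``;
    ``component_map`` holds -1 for background and otherwise an index into
    ``components`` (flat list of ``(lesion_index, KineticModel)``), giving
    the exact generating model of every voxel.
    """

    label_map: np.ndarray
    component_map: np.ndarray
    components: tuple[tuple[int, KineticModel], ...]
    lesion_classes: tuple[KuhlClass, ...]
    malignant: tuple[bool, ...]

    def lesion_mask(self, k: int) -> np.ndarray:
        return self.label_map == k + 1


def _sphere_mask(grid: tuple[int, int, int], center: Sequence[int], radius: float) -> np.ndarray:
    coords = np.indices(grid, dtype=float)
    d2 = sum((coords[i] - center[i]) ** 2 for i in range(3))
    return d2 <= radius**2


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a phantom specification into a 4D series and its ground truth.

    Returns
    -------
    data : ndarray, shape ``grid + (n_frames,)``
        Voxel intensities; each voxel follows its component's kinetic curve
        plus i.i.d. noise of standard deviation ``noise_sigma`` (Gaussian by
        default, Rician if ``spec.rician``).
    truth : GroundTruth

    Identical specs (including the seed) produce bit-identical output;
    changing only the seed changes only the noise realization.
    """
    X, Y, Z = spec.grid
    n = spec.n_frames
    label_map = np.zeros(spec.grid, dtype=np.int16)
    component_map = np.full(spec.grid, -1, dtype=np.int32)
    components: list[tuple[int, KineticModel]] = []

    data = np.empty(spec.grid + (n,), dtype=float)
    data[...] = generate_curve(spec.background, n)

    for k, les in enumerate(spec.lesions):
        mask = _sphere_mask(spec.grid, les.center, les.radius)
        if np.any(label_map[mask] != 0):
            raise PhantomSpecError(f"lesion {k} overlaps an earlier lesion")
        label_map[mask] = k + 1
        vox = np.argwhere(mask)
        # concentric, deterministic component layout: sort voxels by distance
        # to the center (lexicographic tie-break), slice by fractions
        d2 = ((vox - np.asarray(les.center)) ** 2).sum(axis=1)
        order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0], d2))
        vox = vox[order]
        counts = _partition_counts(len(vox), [f for _, f in les.components])
        start = 0
        for (model, _), cnt in zip(les.components, counts):
            comp_idx = len(components)
            components.append((k, model))
            sel = vox[start : start + cnt]
            start += cnt
            if cnt == 0:
                continue
            ix, iy, iz = sel[:, 0], sel[:, 1], sel[:, 2]
            component_map[ix, iy, iz] = comp_idx
            data[ix, iy, iz, :] = generate_curve(model, n)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.rician:
            n1 = rng.normal(0.0, spec.noise_sigma, data.shape)
            n2 = rng.normal(0.0, spec.noise_sigma, data.shape)
            data = np.hypot(data + n1, n2)
        else:
            data = data + rng.normal(0.0, spec.noise_sigma, data.shape)

    truth = GroundTruth(
        label_map=label_map,
        component_map=component_map,
        components=tuple(components),
        lesion_classes=tuple(les.kuhl_class for les in spec.lesions),
        malignant=tuple(les.malignant for les in spec.lesions),
    )
    return data, truth


def _partition_counts(total: int, fractions: Sequence[float]) -> list[int]:
    """Integer voxel counts per component, largest-remainder rounding."""
    raw = np.asarray(fractions, dtype=float) * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts.tolist()


def reference_models(baseline: float = 100.0) -> dict[KuhlClass, KineticModel]:
    """The four canonical kinetic populations used throughout the test bench.

    Amplitudes are chosen so that every population clears the 50 % initial
    enhancement inclusion threshold with margin and so that the four curves
    are mutually well separated in enhancement space (pairwise Euclidean
    distance at least ~0.6): strong straight rise (Ia, 100 %), very strong
    saturating rise (Ib, 140 %), high plateau (II, 110 %), and washout
    (III, 70 % with 35 % loss).
    """
    return {
        KuhlClass.Ia: KineticModel(KuhlClass.Ia, amplitude=1.0, baseline=baseline),
        KuhlClass.Ib: KineticModel(KuhlClass.Ib, amplitude=1.4, baseline=baseline),
        KuhlClass.II: KineticModel(KuhlClass.II, amplitude=1.1, baseline=baseline),
        KuhlClass.III: KineticModel(
            KuhlClass.III, amplitude=0.7, washout_fraction=-0.35, baseline=baseline
        ),
    }


def spec_from_dict(cfg: Mapping) -> PhantomSpec:
    """Build a :class:`PhantomSpec` from a plain (YAML-friendly) mapping.

    Expected keys: ``grid`` (3 ints), optional ``n_frames``, ``noise_sigma``,
    ``rician``, ``seed``, ``baseline``, and ``lesions`` — a list of mappings
    with ``center``, ``radius`` and either flat model keys (``class``,
    ``amplitude``, ``washout_fraction``, ...) or a ``components`` list of
    such mappings each carrying a ``fraction``.
    """
    baseline = float(cfg.get("baseline", 100.0))

    def model_from(d: Mapping) -> KineticModel:
        return KineticModel(
            kuhl_class=KuhlClass(str(d["class"])),
            amplitude=float(d["amplitude"]),
            baseline=float(d.get("baseline", baseline)),
            washout_fraction=float(d.get("washout_fraction", 0.0)),
            initial_fraction=(
                float(d["initial_fraction"]) if "initial_fraction" in d else None
            ),
            curvature=float(d.get("curvature", 3.0)),
        )

    lesions = []
    for ld in cfg.get("lesions", []):
        center = tuple(int(c) for c in ld["center"])
        radius = float(ld["radius"])
        if "components" in ld:
            comps = tuple(
                (model_from(cd), float(cd.get("fraction", 1.0))) for cd in ld["components"]
            )
            lesions.append(Lesion(center, radius, comps))
        else:
            lesions.append(Lesion.homogeneous(center, radius, model_from(ld)))

    kwargs = {}
    if "background" in cfg:
        kwargs["background"] = model_from(cfg["background"])
    return PhantomSpec(
        grid=tuple(int(g) for g in cfg["grid"]),
        lesions=tuple(lesions),
        n_frames=int(cfg.get("n_frames", 6)),
        noise_sigma=float(cfg.get("noise_sigma", 0.0)),
        rician=bool(cfg.get("rician", False)),
        seed=int(cfg.get("seed", 0)),
        **kwargs,
    )
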