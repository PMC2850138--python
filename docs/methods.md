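# Methods

## Model and procedure

The package analyses dynamic contrast-enhanced (DCE) breast MRI series of
n frames (default 6: one precontrast, five postcontrast, nominal 83 s
apart). Every voxel contributes one feature vector: its relative
enhancement course x(τ) = (S(τ) − S(1))/S(1), computed only where the
precontrast signal exceeds a floor (default 1 intensity unit; voxels at or
below it are flagged invalid and excluded from all statistics). Relative
enhancement makes the analysis invariant to global intensity rescaling, so
results do not depend on scanner gain or protocol scaling.

Frame indexing: arrays are 0-based with frame 0 precontrast, so the
clinical "k-th postcontrast frame" is array index k. The initial
enhancement sa_i uses the 2nd postcontrast frame (index 2); the postinitial
course sv_p compares the last frame against the maximum of the 1st and 2nd
postcontrast frames. For protocols with n ≠ 6 the "last frame" is simply
the final acquisition.

The lesion ROI is the connected component (26-neighborhood by default,
6-neighborhood and per-slice 2D growth available) of the voxelwise
sa_i ≥ 50 % mask containing the seed. The comparison is inclusive at the
threshold. Seeds may be placed manually; a seed that misses the mask is
snapped to the nearest masked voxel within 2 voxels (approximate manual
clicks), and the automatic option places the seed at the maximum of the
difference image (frame 4 − frame 1) inside the mask.

Two ratings are computed per lesion:

* **conventional** — the framewise mean raw-signal curve over the ROI is
  rated once;
* **clustered** — the ROI's enhancement vectors are vector-quantized into
  N prototypes (default N = 4), each nonempty prototype's PSIC curve (the
  framewise mean of 100·x over its member voxels) is rated, and the lesion
  receives the maximum prototype score.

Classification rule: washout (III) if sv_p < −10 %, plateau (II) if
|sv_p| ≤ 10 %, steady (type I) if sv_p > +10 %; type I splits into Ia when
the R² of a least-squares line through the postcontrast frames is ≥ 0.98,
else Ib. The ±10 % band follows the conventional reading of the Kuhl
taxonomy and both thresholds are configuration-exposed; they stand in for
the expert radiologist rating such curves receive in clinical practice. A
constant postcontrast course is defined to have R² = 1 (a flat line fits it
perfectly). Scores: Ia=1, Ib=2, II=3, III=4; II and III are malignant-type.

## Vector quantization

Both engines perform online competitive learning: data are visited in a
seeded random permutation per epoch, and each presented vector x moves all
prototypes toward it with method-specific strengths computed from the
pre-update codebook.

* Neural gas: strength α·exp(−k_i/λ), with k_i the rank of prototype i in
  the distance ordering to x (ties broken by prototype index). As λ → 0
  this becomes the online k-means winner-take-all update (asserted at
  λ = 1e−9 in the tests).
* Minimal-free-energy VQ: strength ε·a_i with softmax cooperativities over
  the squared distances at length scale ρ. The softmax is evaluated with
  max-subtraction so the normalization cannot underflow; Σ a_i = 1 holds to
  1e−12. ρ → ∞ gives uniform a_i = 1/N.

Initialization samples N distinct data vectors without replacement
(preferring unique rows, so exactly repeated curves cannot seed duplicate
prototypes); assignment uses the minimal Euclidean distance with ties to
the lowest prototype index; distortion is the mean squared distance to the
winning prototype. With a fixed seed, training is bit-reproducible.

### Annealing schedule

Every schedule parameter decays exponentially,
p(t) = p_init·(p_final/p_init)^(t/(T−1)) over the T = epochs·|data| steps,
reaching its final value exactly at the last step. Defaults, with units and
rationale:

| parameter | default | meaning |
|---|---|---|
| α_init | 0.3 | neural-gas step size; the stable operating point found by the parameter sweep |
| α_final | 0.01·α_init | late training is fine-tuning only |
| λ_init | N/4 | rank-decay constant (prototypes); sweep operating point |
| λ_final | 0.01 | effectively winner-take-all at the end |
| ε_init | 0.3 | MFE step size |
| ε_final | 0.1·ε_init | milder than α on purpose: in deterministic annealing the cooling is carried by ρ, and prototypes must stay mobile while the sharpening softmax separates nearby populations (a 100× decay froze them too early, mean recovery ARI 0.85 → 0.96 on the noisy bench) |
| ρ_init | RMS distance of the data to their mean | the natural data length scale; softmax starts nearly uniform |
| ρ_final | 0.1·ρ_init | hard assignments at the end |
| epochs | 10 | sweep operating point |

The sweep's default grid is α ∈ {0.1, 0.3, 0.5, 0.7, 1.0} × epochs ∈
{1, 10} × λ ∈ {N/6, N/4, N} (30 combinations, containing the reference
point 0.3/10/N/4); the winner minimizes the summed variance over runs of
the extreme prototype descriptors (min/max sa_i, min/max sv_p) — the
simplest scalarization of "small dispersion of the extremes", and
configurable.

## Phantom generator

The phantom emulates what the downstream stages need from real data:
a 3D grid of non-enhancing background (constant baseline, default 100)
containing digital-sphere lesions whose voxels follow parametric Kuhl-type
curves, plus i.i.d. additive Gaussian noise on the raw intensities
(Rician optional; at lesion-typical signal levels the two are nearly
identical, and the Gaussian makes the oracle arithmetic exact).

Curve parameterization: frame 1 reaches baseline·(1 + amplitude·f) with
initial fraction f = 0.5 for the steady types Ia/Ib and f = 1 for II/III;
the remaining frames rise linearly to the peak (Ia), rise along a
normalized saturating exponential with curvature 3 (Ib), hold the plateau
(II), or decline linearly from the peak to peak·(1 + washout_fraction) at
the last frame (III). Consequences worth knowing: a zero-noise plateau
voxel has sa_i = 100·amplitude exactly; an Ia voxel has
sa_i = 62.5·amplitude (it is still rising at frame 2); a washout voxel has
already begun its decline at frame 2.

Heterogeneous lesions carry several kinetic components with fractional
volumes, laid out concentrically (first component innermost) by a
deterministic ordering — so the ground truth is a function of the
specification only, and changing the seed changes only the noise
realization.

The canonical four-population bench uses Ia at 100 % amplitude, Ib at
140 %, II at 110 % and III at 70 % with 35 % washout: every population
clears the 50 % inclusion threshold with margin, and all pairwise
Euclidean separations in enhancement space are ≥ ~0.6 — at least 3× the
per-direction noise at the "moderate" noise level σ = 5 % of baseline, so
the four populations are genuinely distinct yet not trivially far apart.
The simulated cohorts for the diagnostic comparison use 8 benign lesions
(pure Ia or Ib, amplitudes drawn per lesion) and 8 malignant lesions whose
volume is 80 % steady-type with a 20 % concentric washout core, at noise
σ = 2; each lesion is rendered as its own 13×13×10 single-lesion series
and scored by both methods. These sizes (120-voxel ROIs, 16-lesion
cohorts, 20 runs/cohorts per experiment) were chosen as the smallest
configurations at which the multi-run statistics are meaningful.

What the phantom does **not** emulate: pharmacokinetic (Tofts-type)
enhancement physics, motion, coil/bias fields, partial-volume mixtures at
lesion rims, or spatially correlated noise. Passing tests therefore
demonstrate the correctness and stability of the algorithmic chain under
known kinetics, not clinical performance; the original study's
cohort-dependent sensitivities/specificities and ROC areas are outside
what a phantom can establish.

## Numerical choices and degenerate inputs

* Ties everywhere (ranks, assignments, seed snapping) resolve to the
  lowest index / lexicographically smallest voxel, making every stage
  deterministic.
* sa_i requires a positive precontrast value; sv_p a positive early
  maximum — violations raise typed errors rather than returning NaN.
* Empty clusters are dropped from the PSIC set with a logged warning (an
  empty prototype has no member curve to rate); stability tables count
  nonempty prototypes only.
* The 6-point ROC uses "malignant if score ≥ t", t = 1…4, plus the two
  anchor points (sens 1/spec 0 and sens 0/spec 1), integrated
  trapezoidally; on ordinal scores this equals the Mann–Whitney
  concordance, which the tests verify by brute-force pair enumeration.
* ROC areas are reported as computed; an uninformative scorer gives 0.5,
  and an anti-correlated scorer gives < 0.5 (no clamping or flipping).

## Known limitations

* Online single-run VQ retains a small local-minimum rate: on the noisy
  four-population bench the worst of 20 runs reaches ARI ≈ 0.85 while the
  mean is ≈ 0.93–0.96. A restart wrapper (pick lowest distortion) would
  remove this but is deliberately not the default, because the multi-run
  stability analysis is itself the tool for judging reliability.
* The non-divisive online MFE variant implemented here can permanently
  merge prototypes on adversarial geometries (a tight cluster group with a
  far outlier): once two prototypes coincide to machine precision their
  updates are identical forever. The divisive, free-energy-monitored
  formulation that addresses this is out of scope.
* The Ia/Ib split depends on the R² threshold (0.98) of a 5-point line
  fit, which is sensitive at low noise amplitudes; on noisy prototypes the
  steady class tends toward Ib. Both ratings are affected equally, so
  comparisons between methods are fair.
* Lesion masks, classes and scores are per-connected-component; multiple
  lesions in one series are evaluated one seed at a time.
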