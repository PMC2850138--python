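# kineticlust

Unsupervised kinetic-curve analysis for small-lesion evaluation in dynamic
contrast-enhanced (DCE) breast MRI.

## The problem

Dynamic breast MRI acquires a precontrast volume and a series of
postcontrast volumes (here 6 frames, 83 s apart). The shape of a voxel's
time–signal intensity curve carries diagnostic information: steadily rising
curves (Kuhl type Ia straight, Ib curved) are typical of benign lesions,
while plateau (type II) and washout (type III) curves prevail in cancers.
The clinical-standard reading averages the signal curves over a segmented
region of interest (ROI) and rates that single mean curve. For small
lesions of only a few dozen voxels this averaging is dangerous: a minority
washout subpopulation disappears into a benign-looking mean.

`kineticlust` implements the alternative: cluster the individual voxel time
courses *inside* the ROI with vector quantization, rate each prototype
curve, and score the lesion by its most suspicious prototype.

## Method

1. **Preprocessing.** Each raw curve S(τ), τ = 1…n, becomes a relative
   enhancement curve x(τ) = (S(τ) − S(1))/S(1), with the precontrast frame
   as reference — invariant to scanner gain and protocol scaling.
2. **Segmentation.** The initial enhancement
   sa_i = (SI_2nd-post − SI_pre)/SI_pre × 100 % is computed voxelwise; voxels
   with sa_i ≥ 50 % are kept, and a seeded region-growing step extracts the
   connected lesion component (seed manual, or automatic at the maximum of
   the difference image frame 4 − frame 1).
3. **Clustering.** The ROI's enhancement curves are quantized into N
   prototype time courses ("codebook vectors") by either
   * the **neural-gas network**,
     w_i ← w_i + α·exp(−k_i/λ)·(x − w_i), where k_i is the rank of
     prototype i when sorted by distance to x, or
   * **minimal-free-energy VQ** (deterministic annealing),
     w_i ← w_i + ε·a_i·(x − w_i) with softmax cooperativities
     a_i = exp(−‖x−w_i‖²/2ρ²)/Σ_j exp(−‖x−w_j‖²/2ρ²) and ρ annealed
     downward.
   Training visits the data in seeded random order; α, λ, ε, ρ decay
   exponentially from initial to final values. Reference operating point:
   α = 0.3, 10 epochs, λ = N/4, N = 4 clusters.
4. **Classification.** Each cluster's mean percentage signal-intensity
   change (PSIC) curve is rated by the postinitial course
   sv_p = (SI_last − M)/M × 100 %, with M the early-postcontrast maximum:
   washout (III) if sv_p < −10 %, plateau (II) if |sv_p| ≤ 10 %, steady
   (type I) otherwise — split into Ia/Ib by the straightness (R²) of the
   postcontrast course. Classes map to ordinal scores Ia=1, Ib=2, II=3,
   III=4; the lesion score is the maximum over prototypes.
5. **Evaluation.** Multi-run stability tables (class counts over 20 seeded
   runs), a 30-combination parameter sweep minimizing the run-to-run
   dispersion of the prototype descriptors, and 6-point ROC curves over the
   ordinal scores with trapezoidal area A_Z.

Patient data for the original study are not available, so the package ships
a phantom generator (`kineticlust.phantom`) producing 4D series with known
per-voxel kinetics — including kinetically heterogeneous lesions — on which
every stage is validated end to end.

## Worked example

Generate the built-in demo phantom (four radius-3 lesions, one per Kuhl
class, noise σ = 2) and evaluate the washout lesion:

```bash
$ kineticlust simulate --out demo --seed 1
phantom written to demo (4 lesions)

$ printf 'seed_point: [17, 17, 6]\n' > washout.yaml
$ kineticlust run --in demo/series.nii.gz --config washout.yaml --out demo/run --seed 0
ROI 116 voxels | conventional class III (score 4) | clustered lesion score 4

$ cat demo/run/report.csv
cluster_id,members,sa_i,sv_p,linearity,class,score
0,36,53.383493835034336,-34.48876830775252,0.9992594188162516,III,4
1,27,53.94915063455692,-35.86944096160123,0.9987738244949941,III,4
2,29,57.32357707072522,-35.03354421711486,0.9994070311026965,III,4
3,24,59.12749137115731,-34.246215884142714,0.999762870518798,III,4
```

All four prototypes of this homogeneous lesion show ~55 % initial
enhancement followed by ~35 % washout (sv_p ≈ −35 %), i.e. type III,
score 4 — matching the generating model (amplitude 0.7, washout −0.35).
On *mixed* lesions the two columns of the `run` summary diverge: the
conventional ROI-mean score stays benign while the clustered score finds
the washout subpopulation (see `kineticlust.evaluate.cohort_auc_comparison`).

The same stages are available as a library:

```python
from kineticlust import NeuralGasVQ, psic_curves, classify_psic

est = NeuralGasVQ(n_clusters=4, random_state=0).fit(enhancement_vectors)
for p in psic_curves(enhancement_vectors, est.labels_, 4):
    print(p.cluster_id, classify_psic(p.values))
```

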