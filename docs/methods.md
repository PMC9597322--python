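# Methods

This note documents the models, conventions and design choices behind
`ssngrowth`, in the spirit of a methods appendix: what is computed,
under which assumptions, and where the genuinely open decisions were
made.

## Coordinate and data conventions

All volumes are 3D arrays in `(z, y, x)` order with per-axis voxel
spacing in mm and a world origin; `world = origin + index · spacing`
with 0-based indices.  NIfTI I/O transposes to the on-disk `(x, y, z)`
layout.  Intensities are Hounsfield units throughout.

## Measurement

* **Volume** is foreground voxel count times the voxel volume.  No
  partial-volume correction is applied: the voxelized mask *is* the
  object being measured, and the phantom ground truth is defined on
  the same voxelization so that measurement tests are exact rather
  than tolerance-based.
* **Mass** is `V · (A + 1000)/1000` with `A` the mean HU under the
  mask — the water-calibrated linear map from attenuation to density
  (air at −1000 HU is massless).  With `V` in mm³ the mass is in mg.
* **Diameter** is the longest side of the minimum-area rotated
  rectangle circumscribing the lesion on the axial slice with the
  largest foreground area (axial because that is the acquisition
  plane; ties break toward the lowest slice index).  The rectangle is
  fitted to the *outer corners* of the foreground voxels mapped to mm
  (shapely's minimum rotated rectangle over the corner cloud), so an
  axis-aligned `n`-voxel run measures exactly `n` times the in-plane
  spacing and a single voxel has diameter one spacing.  Anisotropic
  in-plane spacing is handled by mapping corners to mm before the
  search; no resampling is performed for measurement.
* **Doubling time** uses the exponential-growth closed form
  `DT = Δt · ln2 / ln(X₂/X₁)`.  Non-increasing metrics have no
  doubling time; this is stored as an explicit missing value (never
  ±inf) and cohort summaries use only DT ∈ [1, 1000] days, so a
  flagged record still contributes to rate statistics while staying
  out of the doubling-time quartiles.
* Cohort summaries report mean ± SD of rates and median (Q1, Q3) of
  clipped doubling times per group, compared with two-sided Welch
  (unequal-variance) t-tests.  Categorical cohort variables are
  compared by Pearson χ² without continuity correction (configurable).

## Growth criterion

Growth is a ≥ 25% mass increase within one year.  The relative mass
increase over the actual inter-exam interval is annualized *linearly*
(`y = ΔM/M · 365/Δt`); compounding is deliberately not applied, so the
rate is interpreted the same way as the raw relative increase rates.
The boundary `y = 0.25` is labelled growth (inclusive reading of "at
25%"); both the threshold and the inclusivity are configurable.  The
regression target fed to the model is this annualized rate `y`; the
loss-weighting cutoff `r = 0.1` used during training is an
independent constant and is *not* the class threshold.

## Phantom simulator

Each phantom is an ellipsoidal lesion in noisy parenchyma.  Lesion
membership is the hard ellipsoid indicator at voxel centres smoothed
by a Gaussian of physical scale `edge_softness` (mm); the ground-truth
mask thresholds membership at 0.5 and the rendered HU blends
parenchyma and lesion attenuation by membership, with additive
Gaussian noise.  Because blending is linear, thresholding a noiseless
rendering at the HU midpoint recovers the ground-truth mask exactly —
this is what makes the end-to-end pipeline test exact.

Defaults: parenchyma −850 HU with σ = 25 HU noise; lesion −650 HU;
initial maximal diameter constrained to the 5–30 mm screening
inclusion window.  Trajectories scale the semi-axes by
`radius_scale_per_year` raised to the elapsed years and drift the
lesion HU linearly; a small random rigid offset per follow-up exam
(default SD 1.5 mm) emulates inter-scan positioning differences.

Ground truth is recorded twice per time point: on the voxelized mask
(volume, mask-mean HU, mass — the exact targets for measurement) and
in closed form on the continuous ellipsoid (for convergence checks).
Voxelized sphere volumes converge to the analytic value at generic
sub-voxel positions (≲2% for radius ≥ 4 voxels); a sphere centred
exactly on a lattice point is a worst case and can exceed this, which
is why cohort phantoms draw sub-voxel-random centres.

### Cohort generator

`generate_cohort` draws stratified growth / non-growth trajectories.
The default prevalence is 7% growth, matching screening cohorts.  The
class-conditional distributions emulate the observed contrast between
growing and stable sub-solid nodules — growers are larger and denser
at baseline (initial diameter 6.5–16 mm vs 5–8 mm; initial mean HU
−650…−500 vs −700…−560) and gain both size (10–25%/year in radius)
and attenuation (+20…+60 HU/year), while stable nodules fluctuate
within ±3%/year and ±10 HU/year.  Under these kinetics the annualized
mass rate lands around 0.4–1.2 for growers and |y| ≲ 0.15 for
non-growers, so generated labels sit well clear of the 0.25 boundary.
Because baseline appearance differs between classes, growth is partly
predictable from a single scan — mirroring the clinical observation
that larger, denser ground-glass lesions are the ones that grow — and
this is what gives the single-time-point (learnable-substitute) model
traction.

What the phantoms do *not* model: lung anatomy (vessels, airways,
pleural contact), part-solid internal structure, scanner kernel and
dose effects, and segmentation error on real lesions.  Passing tests
therefore demonstrate correctness of the computational chain, not
clinical performance.

## Scan pairing

Registration is rigid (6-DOF Euler transform) via SimpleITK: moments
initialization, mean-squares metric, regular-step gradient descent.
A deformable model is unnecessary at VOI scale.  The result carries a
`success` flag from the post-alignment intensity correlation (default
cut 0.5), so structureless inputs are flagged rather than silently
mis-registered.  Lesions are matched across time by mutual nearest
neighbour between transformed centroids with a 10 mm gate; unmatched
lesions are reported.  VOIs are cubic crops (default 32³ voxels)
resampled to 1 mm isotropic, padded with −1000 HU outside the scan.
A fixture segmenter (threshold at background + 3σ or an explicit
threshold, largest component, morphological closing) exists for
phantom pipelines only; real-data segmentation is out of scope.

## Growth prediction model

The encoder is a 3D vision transformer over non-overlapping 8³-voxel
patches of a 32³ VOI (64 tokens), with learned positional embeddings
and pre-norm residual blocks.  The default desk-scale configuration
is 4 layers, 128 dims, 4 heads, MLP ratio 2; a `vit_b` configuration
(12×768) exists for full-scale runs.  Intensities are clipped to
[−1000, 400] HU and scaled to [0, 1].  No augmentation is applied by
default.

Both time points pass through the *same* encoder weights.  Three
embeddings are used: `FG_t`, the mean over all final-layer tokens of
the current VOI (global summary); `FL_t` and `FL_{t−1}`, means over
the tokens whose patch centres fall in the central half-extent cube
(local, nodule-centred summaries — no mask is needed at inference).
Mean pooling was chosen over a class token so that the two branches
are exactly exchangeable (identical inputs give bit-identical local
embeddings) and no global summary of the prior is ever computed — the
surrounding anatomy is essentially static, and only the current scan
contributes global context.  A missing prior is replaced by a trained
substitute vector.

The spatial-temporal mixer stacks the three embeddings as tokens and
applies one token-mixing linear layer across the 3-token axis and one
channel MLP, each residual with layer normalization; the flattened
result feeds a single linear head emitting the scalar rate `p`.  The
head regresses a rate — classification is derived afterwards via the
sharpened logistic map and an operating threshold chosen by maximal
Youden's J on validation outputs (ties toward the smaller threshold).

**Loss.**  Class-weighted smooth-L1 with transition width β = 1
(configurable; the width is a free choice), weight α = 3 on samples
with true rate y ≥ r = 0.1.  With α = 1 the loss reduces exactly to
plain smooth-L1.

**Optimization.**  AdamW with first-moment decay 0.9 (the stated
"momentum"), second-moment decay 0.999, weight decay 0.05, batch 16.
The learning rate warms up linearly from 10⁻⁵ to the scaled peak
`lr · batch/64` (base lr 5·10⁻⁴) over the first 5 epochs, then
follows cosine annealing to 0.  Training is deterministic given the
config seed.

**Why a bespoke autodiff engine.**  The network runs on a compact
reverse-mode tensor autodiff engine (`ssngrowth.nn.autodiff`, ~15
operations, fully gradient-checked) built directly on numpy.  This
keeps the package dependency-light and CPU-only; the engine preserves
float32 end to end (scalar operations do not promote) and uses the
sigmoid-form GELU approximation `x·σ(1.702x)` for speed.

## Radiomics baseline

Features per nodule (≈72 by default, count recorded in metadata):
18 first-order intensity statistics; 14 shape descriptors (marching-
cubes surface, sphericity, compactness, PCA axis lengths, maximal 3D
diameter, …); 25 grey-level co-occurrence summaries and 16 run-length
summaries, both computed in 3D over the 13 unique directions after
fixed-bin (25 HU) discretization under the mask.  Feature selection
is L1-penalized logistic regression with the penalty chosen by
5-fold cross-validated log-loss (seeded folds); the final model is a
ridge-stabilised logistic regression on the selected features, with
standardization statistics fitted on the training split only.  The
baseline uses the current VOI alone; a two-VOI concatenation flag is
available.

## Evaluation

AUC is computed as the Mann–Whitney statistic (ties count ½).
Operating-point metrics use the closed decision rule `score ≥
threshold`; metrics with zero denominators are flagged undefined, not
propagated as NaN.  Confidence intervals are percentile bootstrap
(default B = 2000) resampling at the nodule level; single-class
resamples are redrawn and counted.  BCa correction and per-patient
resampling are not implemented.

## Problem sizes and numerical notes

Desk-scale defaults used by the test battery: cohorts of up to 400
trajectories on 48³ grids at 1 mm; model training on 32³ VOIs for 15
epochs at 30% growth prevalence (a deliberate enrichment — at n = 400
the screening-realistic 7% prevalence leaves too few positives in a
held-out quarter for a stable AUC estimate, while 30% keeps the
imbalance weighting meaningful); bootstrap coverage checks with
B = 1000 over 100 simulated datasets of n = 150.  Epoch counts are a
desk-scale choice: the separable synthetic kinetics converge within
~15 epochs under the warmup + cosine schedule.

Degenerate inputs are contracts, not accidents: empty masks,
single-class label vectors, non-positive baselines, constant-
intensity registration inputs and out-of-volume VOI centres all raise
explicit errors; structureless registration inputs return a
failure flag.

## Known limitations

* The phantom world is geometric; no claim is made about performance
  on clinical CT.
* The minimum-rectangle diameter can differ from maximal in-plane
  Feret diameter conventions used by some software.
* The spatial-temporal mixer is one published-family variant (token
  mix + channel mix); depth and internals are configurable but not
  exhaustively explored.
* Bootstrap CIs are percentile-type and mildly undercover at small n.
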