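# Methods

`shortcutaudit` measures whether an image classifier exploits demographic
shortcuts — incidental, group-correlated image features such as a technician's
metal marker in the corner of a chest radiograph — and mitigates them with a
family of stochastic geometric distortions. This note documents the models,
the synthetic cohorts the tests run on, the numerical choices, and what
passing tests do and do not establish.

## The audit protocol

Four linked experiments, run on subject-disjoint train/validation/test splits:

**A — Association.** Are image labels statistically dependent on demographic
attributes? Two tests per (attribute, label) pair: a Pearson chi-square on the
group × label contingency table, and a permutation test on the in-sample AUC
of a logistic regression predicting the label from one-hot demographic
features. The labels are shuffled (100,000 times by default), the regression
is refitted per shuffle, and the p-value uses the add-one correction
`p = (1 + #{AUC_perm >= AUC_obs}) / (1 + B)`, so it is never exactly zero and
is super-uniform under the null. Because the features are categorical, the
fit runs on grouped sufficient statistics (pattern counts) via Newton/IRLS,
which makes refit-per-permutation affordable.

**B — Demographic classifiability.** Train a classifier to predict the
demographic attribute from the image. A high AUC means group-identifying
features exist and are learnable — candidate shortcuts. The augmented arm is
trained *and evaluated* on distorted images (the distorted dataset is a
dataset; its validation and test splits are distorted too).

**C — Grouped label detection.** Train a multi-label detector (BCE loss),
pick one decision threshold per label by maximising the support-weighted F1
on validation over the grid {0.00, 0.01, …, 1.00} (ties to the smallest
threshold), and evaluate AUC / BCE / ECE / error rate / precision per
demographic group at those shared thresholds. The fairness gap of a metric is
max − min over groups; the macro gap averages per-label gaps without weights.
Test-time augmentation (TTA) scores a test image by the mean of the model's
scores over 3 draws of each of the four distortions (12 ensemble members);
the TTA condition selects its own thresholds from TTA validation scores, since
score averaging changes the score scale.

**D — Task transfer.** Freeze the detector's backbone, fit a fresh linear head
on penultimate features to predict the demographic attribute, and report test
AUC with a percentile bootstrap CI (1000 iterations, seed 2021 by default).
The probe runs under the same augmentation condition as its backbone's
training; features are verified bit-identical before and after probe fitting.

## The distortion family

Rotation, shear, scaling and fisheye warping, with modality presets: rotation
±90° (2D radiograph) or ±10° (3D brain volume), shear ±π/4 or ±π/6 radians
(slope = tan of the angle, horizontal, centre-anchored), scale 0.4–1 or
0.8–1 (shrink about the centre, zero-padded), fisheye coefficient 0.4 with a
uniformly random centre. The fisheye is a normalised barrel map: with radii
normalised so the farthest corner from the centre is at 1, the output at
radius r samples the input at `r(1 + k r²)/(1 + k)` — identity at k = 0,
centre-fixed, strictly monotone (no folding), corners mapping to corners. Its
displacement `r·k(1−r²)/(1+k)` grows with the distance from the centre over
the central field and returns to zero at the rim by construction.

A train-time policy defaults to chaining all four operators in the order
rotate → shear → scale → fisheye with independently drawn parameters, fused
into a single resampling pass (one bilinear/trilinear interpolation through the
composed coordinate field, not four accumulating warps). The chained family is
the default because scale, shear and fisheye are individually
quadrant-preserving for a corner marker; only the chain displaces the token
out of its original quadrant in more than half of the draws (≈58% at the
default 64×64 geometry). Drawing a single operator per image remains available
(`composition_mode="single_random"`); the TTA ensemble always draws
per-method. Training re-samples the distortion every epoch; a fixed
pre-distorted copy of the validation split serves as the early-stopping
target in the augmented arm. Images interpolate bilinearly, masks with
nearest-neighbour; out-of-bounds regions take the fill value 0 and outputs are
clipped back to [0, 1].

## The synthetic cohorts

Cohorts emulate the statistical structure of the real radiograph/MRI data the
audit is designed for, not their appearance. Each of `n_subjects` (default
600) belongs to one categorical group (default three groups at proportions
0.2/0.3/0.5, standing in for race/age-bin/sex) and contributes
`images_per_subject` images (default 3; large radiograph archives average 3–4
images per patient, and per-subject correlation is what makes subject-wise
splitting consequential). Images are 64×64 (2D) or 32³ (3D) floats in [0, 1]
over a flat 0.3 background with Gaussian pixel noise (σ = 0.05), desk-scale
analogues of histogram-equalised (224, 224) radiographs and (96, 96, 96)
brain volumes.

*Disease signal.* Binary labels are drawn per subject with group-conditional
prevalences π[g, l]. The default label set is one group-dependent finding
(π = 0.25/0.50/0.75 across the three groups) and one designed-null finding
(π = 0.5 everywhere). Label l renders as a concentric centred band (label 0 a
disk, label 1 an annulus) at contrast 0.3 — centred shapes are invariant to
every member of the distortion family, so detectability survives
augmentation by construction. Positives render their band with probability
`visibility` (default 0.8), emulating the noise of report-derived
(NLP-extracted) labels: an invisible positive is indistinguishable from a
negative, which (i) caps every model's detection AUC at the same level
(~0.9), and (ii) is exactly what makes a group-revealing shortcut *useful* —
the group carries prevalence information the pixels do not. An optional
severity continuum (`contrast_sd`, `mimic_contrast`) makes band intensity
graded and negatives faintly mimicked; it is off by default because the graded
version of the distortion-invariant detection task does not converge at desk
scale.

*Shortcut.* By default a 7×7 bright token (contrast 0.4) sits in one of the
four (2D) / eight (3D) corners, the corner a deterministic function of the
group, present for a fraction `leak_rate` of subjects (default 1). Border
stripes and per-group global intensity offsets are available alternatives.
The cohort carries ground-truth shortcut and disease masks for every sample.

Everything is deterministic given the spec's seed. What the generator does
*not* model: anatomy and photorealism, scanner/site effects, continuous age,
label co-occurrence structure, and — deliberately — the unknown mechanism by
which real images encode demographics; the three shortcut kinds are
controllable stand-ins, so a passing audit here shows the machinery detects
and mitigates *planted geometric* shortcuts, not that it would detect any
real-world encoding.

## Models and training

The shipped reference classifier is a small strided CNN written directly in
numpy with explicit backward passes: 3×3 (or 3×3×3) stride-2 conv + ReLU
blocks with channel widths (16, 32, 64), global average pooling (the
penultimate features), and one linear head (softmax for mutually exclusive
demographics, sigmoid for multi-label findings). Hand-written backprop is what
exposes input gradients (integrated gradients), conv activations and their
gradients (Grad-CAM), and a gradient-injection point at the penultimate layer
(adversarial and distribution-matching penalties). The narrower (8, 16, 32)
variant underfits the distortion-invariant detection task. Anything else can
be audited by implementing the same adapter contract.

Optimisation: Adam, initial learning rate 1e-3 decayed by 5% every 2 epochs,
early stopping on validation loss with a strict improvement threshold of 1e-5,
best-validation weights restored. Modality presets follow the audit protocol
(batch 128, patience 4 within 15 epochs for 2D; batch 16, patience 10 within
80 for 3D). Those budgets assume ~1e5-image datasets; at desk scale they give
a few dozen gradient updates, so the `"desk"` preset keeps the lr/decay/
early-stop structure at batch 16 with more epochs (30 for demographic
classification; the experiment pipeline gives detectors up to 60 with patience
12, the budget at which the distortion-invariant task converges on
600-subject cohorts).

## Debiasing comparators

Balanced subject-wise subsampling to the minority group's count; per-group
stratified models with group-routed inference; gradient-reversal adversarial
training (two-layer adversary on penultimate features, one adversary step per
batch, main model receives −λ·∂CE/∂features); distribution-matching penalties
γ·D between per-group score batches with D either a biased RBF MMD²
(median-heuristic bandwidth, treated as a per-batch constant when
differentiating) or the squared difference of group mean scores; and an
augmented-Lagrangian scheme on the spread of per-group mean BCE risks
(model step on task + μc + (ρ/2)c², multiplier step μ ← μ + η·c per epoch,
abort if |μ| > 1e6). Default weights λ = γ = 1, η = 0.01, ρ = 1 — the
comparison methods' sources do not pin these, so they are exposed in
`DebiasConfig`. Every method at weight 0 reproduces the baseline trajectory
bit-for-bit under a shared seed (penalty hooks consume no model-path
randomness), which the tests enforce to 1e-6 on the final validation loss.

## Interpretation

Grad-CAM pools the target score's gradient over the last conv block's spatial
axes, weights the activations, rectifies, upsamples to the input and rescales
to [0, 1]. Integrated gradients use a midpoint Riemann path from a zero
baseline (50 steps by default); completeness (attributions summing to the
score difference) tightens with steps and sits within 5% at 200 steps for the
shipped models. Cohort-level mean saliency averages |IG| over images and
reports a density histogram of per-pixel magnitudes. The discordant-case
selector returns exactly the samples where the baseline model identifies the
demographic attribute (argmax for multi-class, 0.5 for binary), the mitigated
model does not, and both predict every label correctly at the global
thresholds.

## Numerical and design choices

- AUC is the Mann–Whitney rank statistic (ties count ½), identical to the
  trapezoidal area under the empirical ROC; tests cross-check against
  exhaustive pair enumeration and scikit-learn.
- ECE uses 10 equal-width right-closed bins on [0, 1] (1.0 falls in the last
  bin); empty bins contribute zero.
- BCE clips scores to [1e-7, 1 − 1e-7].
- Precision with no predicted positives is NaN with a warning and is excluded
  from gaps rather than imputed — imputing 0 would manufacture disparities.
- The fairness gap is max − min over finite group values (a mean-pairwise
  absolute difference is available); groups with one truth class have their
  AUC omitted with a warning.
- The bootstrap resamples individual test samples with replacement (subjects
  optionally), drops undefined replicates with a count, and takes 2.5/97.5
  percentiles; it is bit-reproducible given its seed.
- Exact quarter-turn rotations snap the affine matrix/offset against float
  noise (cos 90° ≈ 6e-17) so they reduce to index permutations.
- The subject-wise splitter uses largest-remainder rounding (counts within one
  subject of the exact targets, exact when integral) and refuses any split
  that would be empty.

## What the end-to-end audit shows

On the default cohort (600 subjects, three groups, deterministic corner
token), across three seeds: the demographic attribute is perfectly readable
from raw images (AUC ≈ 1.0) and drops by ≈ 0.4 when training and testing on
distorted images; the detector's penultimate features expose the group to a
linear probe (AUC ≈ 0.99) unless the backbone was trained under distortion
(≈ 0.67); label detection is unharmed (macro AUC ≈ 0.92 both arms); and the
error-rate fairness gap of the lowest-disparity augmented condition is below
the baseline's in every seed. These are directional reproductions of the
audit's full-scale findings at ~1/300 of the data and a far smaller model;
the absolute numbers are not comparable to the real-data tables, and on an
iid synthetic cohort a converged baseline's thresholded decisions can
legitimately tie the augmented model's on the group-dependent label (the
informative token acts as a prevalence prior), which is why the gap
comparison follows the audit tables' best-augmented-condition convention.

## Known limitations

- The numpy backend is CPU-only and desk-scale; it is a reference
  implementation of the adapter contract, not a training framework.
- The permutation test is in-sample, as the protocol describes a single fit
  per attribute set; with richer feature spaces an out-of-sample variant would
  be preferable.
- 3D rotations and shears act in the axial plane only (the small-angle
  volumetric preset); per-axis 3D rotations are not implemented.
- Multi-group FairALM uses the max pairwise risk difference; other constraint
  aggregations are not provided.
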