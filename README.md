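# shortcutaudit

Audit and mitigate **demographic shortcut learning** in medical image
classifiers.

Deep models trained on radiographs or brain MRI can read a patient's race,
age band or sex off the image and quietly use that information as a shortcut
when detecting findings — producing predictions whose error rates, calibration
and ranking quality differ across demographic groups. `shortcutaudit`
implements a four-experiment audit of this failure mode and a mitigation based
on stochastic geometric distortion, exercisable end-to-end on synthetic
cohorts with *planted, ground-truth* shortcuts:

- **A — association**: chi-square and permutation-AUC tests of dependence
  between demographic attributes and image labels,
  `p = (1 + #{AUC_perm ≥ AUC_obs}) / (1 + 100 000)`;
- **B — demographic classifiability**: how well a CNN predicts the group from
  the image (macro one-vs-rest AUC);
- **C — grouped detection**: multi-label finding detection with per-label
  weighted-F1 thresholds, test-time-augmentation ensembling (mean of 12
  distorted copies), and fairness gaps
  `Δm = max_g m_g − min_g m_g` for m ∈ {AUC, BCE, ECE, error rate, precision}
  with seeded bootstrap CIs;
- **D — task transfer**: freeze the detector's backbone, fit a linear probe on
  penultimate features, and measure how much demographic information the
  representation leaked.

The mitigation distorts every image with random rotation (±90° for 2D
radiographs, ±10° for 3D volumes), shear (±π/4 / ±π/6 radians), scaling
(0.4–1 / 0.8–1) and fisheye warping
(`r ↦ r(1 + 0.4 r²)/1.4` about a random centre), at train time and/or as a
test-time ensemble. Geometric distortion destroys *position-coded* incidental
features (a corner marker lands outside its original quadrant in most draws)
while sparing centred anatomy-like signals — no demographic labels required,
no retraining needed for the test-time variant.

The built-in cohort generator plants a configurable shortcut (corner token,
border marker, or global intensity offset) whose geometry follows the group,
with group-dependent finding prevalences and report-style label noise, plus
ground-truth masks — so every audit step can be verified against a known
mechanism. Real data in PNG/TIFF (2D) or NIfTI (3D) with a `cohort.csv` table
loads through the same interface.

## Worked example

```python
import numpy as np
import shortcutaudit as sa

# a 600-subject cohort, 3 groups, deterministic corner-token shortcut
cohort = sa.generate_cohort(sa.CohortSpec(seed=2021))
train, val, test = sa.split_by_subject(cohort, (0.6, 0.1, 0.3), seed=2021)

# Experiment B: is the group readable from the image?
sched = sa.preset_schedule("desk", seed=0)
net = sa.reference_small_cnn((64, 64), 3, head="softmax", seed=0)
sa.train_demographic_classifier(train, val, net, sched,
                                rng=np.random.default_rng(0))
auc_plain = sa.macro_ovr_auc(net.predict_scores(test.images), test.group_codes)

aug = sa.preset_policy("cxr")
net_aug = sa.reference_small_cnn((64, 64), 3, head="softmax", seed=0)
sa.train_demographic_classifier(train, val, net_aug, sched, policy=aug,
                                rng=np.random.default_rng(0))
from shortcutaudit.harness import distort_images
distorted = distort_images(test, aug, np.random.default_rng(1))
auc_aug = sa.macro_ovr_auc(net_aug.predict_scores(distorted), test.group_codes)
print(f"group AUC: {auc_plain:.3f} plain vs {auc_aug:.3f} distorted")
```

```
group AUC: 1.000 plain vs 0.771 distorted
```

The planted corner token makes the group perfectly predictable (AUC 1.000);
under the distortion family the same architecture loses most of that ability
(0.771 here; ~0.5–0.6 over longer training runs in the full pipeline) — the
positional shortcut no longer works. The full pipeline (association tests, grouped
detection with fairness gaps and TTA, transfer probes) runs as one call:

```python
manifest = sa.run_experiment({"seed": 2021}, out_dir="audit_out")
print(manifest.results["summary"])
```

which on the same cohort prints (values rounded)

```
demographic_auc_drop        0.478   # Experiment B, plain minus distorted
probe_auc_gap               0.352   # Experiment D, feature leakage removed
label_auc_drop              0.020   # Experiment C, detection barely affected
error_rate_gap_baseline     0.088   # macro error-rate gap, no augmentation
error_rate_gap_best_augmented 0.058 # lowest gap among augmented conditions
```

— the audit's signature pattern: augmentation erases demographic
readability and representation leakage and narrows the error-rate disparity,
at essentially no cost to detection itself.

A command-line interface covers the same pipeline
(`shortcutaudit simulate | augment | assoc | train | probe | evaluate |
interpret | run`); classical debiasing baselines (balanced subsampling,
per-group models, adversarial training, MMD/mean distribution matching,
augmented-Lagrangian risk matching) plug into the same trainer for
comparison, and `shortcutaudit.interpret` provides Grad-CAM, integrated
gradients, cohort mean-saliency maps and the discordant-case selector.

See `docs/methods.md` for the models, assumptions, and numerical choices.

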