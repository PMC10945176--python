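"""Experiment harness: demographic classification, label detection with
weighted-F1 thresholding and test-time augmentation, and the frozen-backbone
task-transfer probe.

The three measurements this module provides, in audit order:

* How well can a classifier read the demographic group straight off the image?
  (``train_demographic_classifier``) — a high AUC means group-identifying
  features exist and are learnable, i.e. potential shortcuts.
* How does a label detector perform per group, at thresholds chosen to maximise
  the weighted F1 on validation, optionally averaging scores over a 12-member
  test-time-augmentation ensemble? (``train_label_detector``,
  ``select_thresholds``, ``predict_with_tta``)
* What do the detector's penultimate features still encode about the group?
  (``task_transfer_probe``) — the backbone is frozen, a fresh linear head is
  fitted on the features, and its test AUC with a 1000-iteration bootstrap CI
  quantifies demographic leakage into the representation.

All splits are guarded against subject leakage before any fitting.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np

from .augment import AugmentationPolicy, make_tta_ensemble
from .backend import LinearModel, ModelAdapter, TrainSchedule, preset_schedule, reference_small_cnn
from .metrics import BootstrapConfig, ScoreSet, auc, bootstrap_ci, macro_ovr_auc
from .synthetic import SyntheticCohort

__all__ = [
    "TrainSchedule",
    "preset_schedule",
    "ThresholdSet",
    "check_subject_disjoint",
    "train_demographic_classifier",
    "train_label_detector",
    "select_thresholds",
    "predict_with_tta",
    "task_transfer_probe",
    "scoreset_from_cohort",
    "reference_small_cnn",
]


@dataclass(frozen=True)
class ThresholdSet:
    """Per-label decision thresholds in [0, 1]."""

    per_label: dict

    def __post_init__(self):
        for k, v in self.per_label.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"threshold for {k!r} outside [0, 1]: {v}")

    def as_array(self, label_names) -> np.ndarray:
        return np.array([self.per_label[l] for l in label_names], dtype=float)


def check_subject_disjoint(*cohorts: SyntheticCohort) -> None:
    """Raise if any subject appears in more than one of the given cohorts."""
    seen: dict = {}
    for i, c in enumerate(cohorts):
        for s in np.unique(c.subject_id):
            if s in seen:
                raise ValueError(
                    f"subject {s} appears in cohorts {seen[s]} and {i}: subject leakage"
                )
            seen[s] = i


# ---------------------------------------------------------------------------
# training entry points
# ---------------------------------------------------------------------------

def train_demographic_classifier(
    train: SyntheticCohort,
    val: SyntheticCohort,
    adapter: ModelAdapter,
    schedule: TrainSchedule,
    policy: AugmentationPolicy | None = None,
    rng: np.random.Generator | None = None,
) -> ModelAdapter:
    """Fit the adapter to predict the demographic group from the image."""
    check_subject_disjoint(train, val)
    ytr, yva = train.group_codes, val.group_codes
    if len(np.unique(ytr)) < 2:
        raise ValueError("demographic training target has a single class")
    adapter.fit(train.images, ytr, val.images, yva, schedule, policy=policy, rng=rng)
    return adapter


def train_label_detector(
    train: SyntheticCohort,
    val: SyntheticCohort,
    adapter: ModelAdapter,
    schedule: TrainSchedule,
    policy: AugmentationPolicy | None = None,
    rng: np.random.Generator | None = None,
    penalty=None,
) -> ModelAdapter:
    """Fit the adapter on the multi-label binary targets (BCE loss)."""
    check_subject_disjoint(train, val)
    for j, name in enumerate(train.spec.label_names):
        classes = np.unique(train.labels[:, j])
        if len(classes) < 2:
            raise ValueError(
                f"label {name!r} has a single class ({classes.tolist()}) in the "
                "training split; remove it or regenerate the cohort"
            )
    adapter.fit(train.images, train.labels.astype(np.float32),
                val.images, val.labels.astype(np.float32),
                schedule, policy=policy, rng=rng, penalty=penalty,
                groups_train=train.group)
    return adapter


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def _weighted_f1(y: np.ndarray, pred: np.ndarray) -> float:
    """Support-weighted F1 over the positive and negative class (zero-division -> 0)."""
    out = 0.0
    n = len(y)
    for cls in (0, 1):
        tp = np.sum((pred == cls) & (y == cls))
        fp = np.sum((pred == cls) & (y != cls))
        fn = np.sum((pred != cls) & (y == cls))
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom > 0 else 0.0
        out += (np.sum(y == cls) / n) * f1
    return float(out)


def select_thresholds(scores: ScoreSet | np.ndarray, truths=None,
                      label_names=None) -> ThresholdSet:
    """Per-label threshold maximising weighted F1 on a 101-point grid.

    The grid is {0.00, 0.01, ..., 1.00}; ties break toward the smallest
    threshold.  A label without positives gets threshold 0.5 with a warning.
    Accepts a validation ScoreSet, or raw (scores, truths) arrays.
    """
    if isinstance(scores, ScoreSet):
        s_mat, y_mat, names = scores.scores, scores.truths, scores.label_names
    else:
        s_mat = np.atleast_2d(np.asarray(scores, dtype=float))
        y_mat = np.atleast_2d(np.asarray(truths))
        if s_mat.shape[0] == 1 and s_mat.shape[1] > 1 and y_mat.shape == s_mat.shape:
            s_mat, y_mat = s_mat.T, y_mat.T
        names = label_names or tuple(f"label_{j}" for j in range(s_mat.shape[1]))
    grid = np.round(np.linspace(0.0, 1.0, 101), 2)
    out = {}
    for j, name in enumerate(names):
        y = y_mat[:, j].astype(int)
        if y.sum() == 0:
            warnings.warn(f"label {name!r} has no positives in validation; threshold = 0.5")
            out[name] = 0.5
            continue
        f1s = np.array([_weighted_f1(y, (s_mat[:, j] > t).astype(int)) for t in grid])
        out[name] = float(grid[int(np.argmax(f1s))])  # argmax returns first max
    return ThresholdSet(out)


# ---------------------------------------------------------------------------
# test-time augmentation
# ---------------------------------------------------------------------------

def distort_images(images, policy: AugmentationPolicy,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """One policy draw per image (the 'distorted dataset' condition)."""
    from .augment import apply_policy

    if isinstance(images, SyntheticCohort):
        images = images.images
    rng = np.random.default_rng() if rng is None else rng
    return np.stack([apply_policy(im, policy, rng)[0] for im in np.asarray(images)])


def predict_with_tta(
    adapter: ModelAdapter,
    images,
    policy: AugmentationPolicy,
    reps_per_method: int = 3,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """TTA scores: the arithmetic mean of the adapter's scores over the
    ``4 * reps_per_method`` distorted copies of each input (12 by default).

    Accepts an image stack or a SyntheticCohort (scored on its images).
    Returns an (N, n_outputs) score array.
    """
    if isinstance(images, SyntheticCohort):
        images = images.images
    images = np.asarray(images)
    rng = np.random.default_rng() if rng is None else rng
    n_members = 4 * reps_per_method
    stack = []
    for img in images:
        stack.extend(make_tta_ensemble(img, policy, reps_per_method, rng))
    scores = adapter.predict_scores(np.stack(stack).astype(np.float32))
    return scores.reshape(len(images), n_members, -1).mean(axis=1)


def scoreset_from_cohort(cohort: SyntheticCohort, scores: np.ndarray,
                         attribute: str = "group") -> ScoreSet:
    """Join a score matrix for the cohort's labels onto its annotations."""
    return ScoreSet(
        sample_id=cohort.sample_id,
        scores=np.asarray(scores, dtype=float),
        truths=cohort.labels,
        label_names=cohort.spec.label_names,
        groups={attribute: cohort.group},
        subject_id=cohort.subject_id,
    )


# ---------------------------------------------------------------------------
# task transfer
# ---------------------------------------------------------------------------

def _feature_hash(feats: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(feats, dtype=np.float32).tobytes()).hexdigest()


@dataclass
class ProbeResult:
    auc: float
    ci_low: float
    ci_high: float
    scores: np.ndarray           # (N_test, n_classes)
    codes: np.ndarray            # (N_test,) integer attribute codes
    probe: LinearModel


def task_transfer_probe(
    adapter: ModelAdapter,
    train: SyntheticCohort,
    val: SyntheticCohort,
    test: SyntheticCohort,
    attribute: str = "group",
    bootstrap: BootstrapConfig = BootstrapConfig(),
    schedule: TrainSchedule | None = None,
    seed: int = 0,
    policy: AugmentationPolicy | None = None,
    rng: np.random.Generator | None = None,
) -> ProbeResult:
    """Freeze the backbone, fit a fresh linear head on penultimate features to
    predict the demographic attribute, and report test AUC with a bootstrap CI.

    ``policy`` applies the probe under the same augmentation condition as the
    backbone's training: when given, every split's images are distorted once
    before feature extraction.  Verifies that the backbone's features are
    bit-identical before and after the probe fit (the freeze contract).
    """
    check_subject_disjoint(train, val, test)
    if attribute != "group":
        raise ValueError("synthetic cohorts carry a single grouping attribute 'group'")
    codes_tr, codes_va, codes_te = train.group_codes, val.group_codes, test.group_codes
    if len(np.unique(codes_tr)) < 2:
        raise ValueError("probe attribute is constant on the training split")

    if policy is not None:
        rng = np.random.default_rng(seed) if rng is None else rng
        imgs = [distort_images(c, policy, rng) for c in (train, val, test)]
    else:
        imgs = [train.images, val.images, test.images]
    f_tr = adapter.penultimate_features(imgs[0])
    f_va = adapter.penultimate_features(imgs[1])
    f_te = adapter.penultimate_features(imgs[2])
    hash_before = _feature_hash(f_te)

    n_classes = int(max(codes_tr.max(), codes_va.max(), codes_te.max())) + 1
    head = "softmax" if n_classes > 2 else "sigmoid"
    probe = LinearModel(f_tr.shape[1], n_classes if head == "softmax" else 1,
                        head=head, seed=seed)
    if schedule is None:
        schedule = TrainSchedule(batch_size=64, initial_lr=0.01, patience=10,
                                 max_epochs=100, seed=seed)
    ytr = codes_tr if head == "softmax" else codes_tr.astype(np.float32)[:, None]
    yva = codes_va if head == "softmax" else codes_va.astype(np.float32)[:, None]
    probe.fit(f_tr, ytr, f_va, yva, schedule)

    if _feature_hash(adapter.penultimate_features(imgs[2])) != hash_before:
        raise AssertionError("backbone features changed during probe fitting")

    scores = probe.predict_scores(f_te)
    point = macro_ovr_auc(scores, codes_te)
    # bootstrap the macro one-vs-rest AUC over test samples
    truths = np.stack([(codes_te == c).astype(int) for c in range(scores.shape[1])], axis=1) \
        if scores.shape[1] > 1 else (codes_te[:, None] == 1).astype(int)
    ss = ScoreSet(
        sample_id=test.sample_id,
        scores=scores,
        truths=truths,
        label_names=tuple(f"class_{c}" for c in range(scores.shape[1])),
        subject_id=test.subject_id,
    )

    def macro_auc_stat(sub: ScoreSet) -> float:
        vals = []
        for c in range(sub.scores.shape[1]):
            y = sub.truths[:, c]
            if 0 < y.sum() < len(y):
                vals.append(auc(sub.scores[:, c], y))
        if not vals:
            raise ValueError("degenerate replicate")
        return float(np.mean(vals))

    ci = bootstrap_ci(macro_auc_stat, ss, bootstrap)
    return ProbeResult(auc=float(point), ci_low=ci["ci_low"], ci_high=ci["ci_high"],
                       scores=scores, codes=codes_te, probe=probe)
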