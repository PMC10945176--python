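"""Performance and fairness metrics with seeded bootstrap confidence intervals.

Threshold-free metrics: AUC (Mann-Whitney form, ties counted one half), binary
cross-entropy and expected calibration error.  Threshold-required metrics:
error rate and precision, the operational forms of equalised odds and equal
opportunity.  Per-group evaluation always reuses the SAME global thresholds so
group differences reflect the model, not the operating point.

The fairness gap of a metric is the spread max - min over groups (a
mean-pairwise absolute difference is available behind ``gap_method``), and the
macro-averaged gap is the unweighted mean of per-label gaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

__all__ = [
    "ScoreSet",
    "BootstrapConfig",
    "GapReport",
    "auc",
    "bce",
    "ece",
    "error_rate",
    "precision",
    "group_metrics",
    "fairness_gap",
    "macro_average_gap",
    "bootstrap_ci",
    "roc_with_cutoff",
    "gap_report",
    "macro_ovr_auc",
]

METRIC_NAMES = ("auc", "bce", "ece", "error_rate", "precision")


@dataclass
class ScoreSet:
    """Per-sample prediction scores joined to truths and group assignments."""

    sample_id: np.ndarray                 # (N,)
    scores: np.ndarray                    # (N, L) in [0, 1]
    truths: np.ndarray                    # (N, L) in {0, 1}
    label_names: tuple[str, ...]
    groups: dict[str, np.ndarray] = field(default_factory=dict)  # attr -> (N,)
    subject_id: np.ndarray | None = None

    def __post_init__(self):
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        self.truths = np.atleast_2d(np.asarray(self.truths))
        if self.scores.shape[0] == 1 and len(self.sample_id) != 1:
            self.scores = self.scores.T
            self.truths = self.truths.T
        n = len(self.sample_id)
        if self.scores.shape != (n, len(self.label_names)):
            raise ValueError(f"scores shape {self.scores.shape} != (n_samples, n_labels)")
        if self.truths.shape != self.scores.shape:
            raise ValueError("truths shape differs from scores")
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("scores must lie in [0, 1]")
        if not np.isin(self.truths, (0, 1)).all():
            raise ValueError("truths must be binary")
        for attr, vals in self.groups.items():
            if len(vals) != n:
                raise ValueError(f"group attribute {attr!r} has wrong length")

    def __len__(self) -> int:
        return len(self.sample_id)

    def subset(self, idx) -> "ScoreSet":
        idx = np.asarray(idx)
        return ScoreSet(
            sample_id=np.asarray(self.sample_id)[idx],
            scores=self.scores[idx],
            truths=self.truths[idx],
            label_names=self.label_names,
            groups={a: np.asarray(v)[idx] for a, v in self.groups.items()},
            subject_id=None if self.subject_id is None else np.asarray(self.subject_id)[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        d = {"sample_id": self.sample_id}
        if self.subject_id is not None:
            d["subject_id"] = self.subject_id
        for a, v in self.groups.items():
            d[f"group_{a}"] = v
        for j, name in enumerate(self.label_names):
            d[f"score_{name}"] = self.scores[:, j]
            d[f"label_{name}"] = self.truths[:, j]
        return pd.DataFrame(d)


@dataclass(frozen=True)
class BootstrapConfig:
    iterations: int = 1000
    seed: int = 2021
    unit: str = "sample"  # or "subject"

    def validate(self):
        if self.iterations < 1:
            raise ValueError("bootstrap iterations must be >= 1")
        if self.unit not in ("sample", "subject"):
            raise ValueError(f"unknown resampling unit {self.unit!r}")


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def auc(scores: np.ndarray, truths: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Equals P(score_pos > score_neg) + 0.5 * P(tie) over all positive/negative
    pairs, which is exactly the trapezoidal area under the empirical ROC.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truths = np.asarray(truths).ravel()
    pos = truths == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("auc requires both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def bce(scores: np.ndarray, truths: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy with scores clipped to [eps, 1-eps]."""
    s = np.clip(np.asarray(scores, dtype=float).ravel(), eps, 1.0 - eps)
    y = np.asarray(truths, dtype=float).ravel()
    return float(-np.mean(y * np.log(s) + (1.0 - y) * np.log(1.0 - s)))


def ece(scores: np.ndarray, truths: np.ndarray, n_bins: int = 10) -> float:
    """Expected calibration error over equal-width, right-closed bins on [0, 1]."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(truths, dtype=float).ravel()
    idx = np.clip(np.ceil(s * n_bins).astype(int) - 1, 0, n_bins - 1)
    total = len(s)
    out = 0.0
    for b in range(n_bins):
        m = idx == b
        nb = int(m.sum())
        if nb == 0:
            continue
        out += (nb / total) * abs(y[m].mean() - s[m].mean())
    return float(out)


def error_rate(scores: np.ndarray, truths: np.ndarray, threshold: float) -> float:
    """(FP + FN) / N at the given decision threshold (predict 1 when score > t)."""
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(truths).ravel()
    pred = (s > threshold).astype(int)
    return float(np.mean(pred != y))


def precision(scores: np.ndarray, truths: np.ndarray, threshold: float) -> float:
    """TP / (TP + FP); returns NaN (with a warning) when nothing is predicted positive."""
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(truths).ravel()
    pred = s > threshold
    denom = int(pred.sum())
    if denom == 0:
        warnings.warn("precision undefined: no predicted positives; returning NaN")
        return float("nan")
    return float(np.sum(pred & (y == 1)) / denom)


# ---------------------------------------------------------------------------
# grouped evaluation
# ---------------------------------------------------------------------------

def group_metrics(scoreset: ScoreSet, attribute: str, thresholds) -> pd.DataFrame:
    """All five metrics per (group, label) using the same global thresholds.

    ``thresholds`` is a mapping label -> threshold, a sequence aligned with
    ``scoreset.label_names``, or a scalar.  Groups with a single truth class get
    NaN AUC with a warning.
    """
    if attribute not in scoreset.groups:
        raise KeyError(f"scoreset has no group attribute {attribute!r}")
    thr = _threshold_vector(thresholds, scoreset.label_names)
    gvals = np.asarray(scoreset.groups[attribute])
    rows = []
    for g in np.unique(gvals):
        m = gvals == g
        for j, label in enumerate(scoreset.label_names):
            s, y = scoreset.scores[m, j], scoreset.truths[m, j]
            if len(np.unique(y)) < 2:
                warnings.warn(f"group {g!r}, label {label!r}: one truth class; AUC omitted")
                a = float("nan")
            else:
                a = auc(s, y)
            rows.append({
                "group": g, "label": label, "n": int(m.sum()),
                "auc": a, "bce": bce(s, y), "ece": ece(s, y),
                "error_rate": error_rate(s, y, thr[j]),
                "precision": precision(s, y, thr[j]),
            })
    return pd.DataFrame(rows)


def _threshold_vector(thresholds, label_names) -> np.ndarray:
    if np.isscalar(thresholds):
        return np.full(len(label_names), float(thresholds))
    if isinstance(thresholds, dict):
        return np.array([float(thresholds[l]) for l in label_names])
    if hasattr(thresholds, "per_label"):  # ThresholdSet
        return np.array([float(thresholds.per_label[l]) for l in label_names])
    arr = np.asarray(thresholds, dtype=float)
    if arr.shape != (len(label_names),):
        raise ValueError("thresholds length differs from label_names")
    return arr


def fairness_gap(values: Sequence[float], method: str = "max_min") -> float:
    """Spread of a metric across groups: max - min (default) over finite values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError("fairness_gap needs at least two finite group values")
    if method == "max_min":
        return float(v.max() - v.min())
    if method == "mean_pairwise":
        diffs = np.abs(v[:, None] - v[None, :])
        iu = np.triu_indices(len(v), k=1)
        return float(diffs[iu].mean())
    raise ValueError(f"unknown gap method {method!r}")


def macro_average_gap(per_label_gaps: Sequence[float]) -> float:
    """Unweighted mean of per-label gaps."""
    v = np.asarray(per_label_gaps, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValueError("no finite per-label gaps")
    return float(v.mean())


def bootstrap_ci(
    statistic: Callable[[ScoreSet], float],
    scoreset: ScoreSet,
    config: BootstrapConfig = BootstrapConfig(),
) -> dict:
    """Seeded percentile bootstrap of an arbitrary ScoreSet statistic.

    Resamples with replacement from the whole set (units = samples, or whole
    subjects when ``config.unit == 'subject'``); replicates where the statistic
    is undefined are dropped and counted.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = len(scoreset)
    reps, dropped = [], 0
    if config.unit == "subject":
        if scoreset.subject_id is None:
            raise ValueError("subject-unit bootstrap requires subject_id")
        subjects = np.unique(scoreset.subject_id)
        by_subj = {s: np.where(scoreset.subject_id == s)[0] for s in subjects}
    for _ in range(config.iterations):
        if config.unit == "sample":
            idx = rng.integers(0, n, size=n)
        else:
            pick = rng.choice(subjects, size=len(subjects), replace=True)
            idx = np.concatenate([by_subj[s] for s in pick])
        try:
            val = statistic(scoreset.subset(idx))
        except (ValueError, ZeroDivisionError):
            dropped += 1
            continue
        if np.isnan(val):
            dropped += 1
            continue
        reps.append(val)
    if not reps:
        raise ValueError("all bootstrap replicates were undefined")
    reps = np.asarray(reps)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return {"mean": float(reps.mean()), "ci_low": float(lo), "ci_high": float(hi),
            "n_dropped": dropped, "n_replicates": len(reps)}


def roc_with_cutoff(scoreset: ScoreSet, attribute: str, thresholds) -> dict:
    """Per-group ROC point lists plus the (FPR, TPR) operating point at the
    global threshold, per label."""
    if attribute not in scoreset.groups:
        raise KeyError(f"scoreset has no group attribute {attribute!r}")
    thr = _threshold_vector(thresholds, scoreset.label_names)
    gvals = np.asarray(scoreset.groups[attribute])
    out = {}
    for g in np.unique(gvals):
        m = gvals == g
        out[g] = {}
        for j, label in enumerate(scoreset.label_names):
            s, y = scoreset.scores[m, j], scoreset.truths[m, j]
            if len(np.unique(y)) < 2:
                warnings.warn(f"group {g!r}, label {label!r}: one truth class; ROC omitted")
                continue
            fpr, tpr, _ = roc_curve(y, s)
            pred = s > thr[j]
            pos, neg = y == 1, y == 0
            op = (float(np.mean(pred[neg])), float(np.mean(pred[pos])))  # (FPR, TPR)
            out[g][label] = {"fpr": fpr, "tpr": tpr, "cutoff_point": op,
                             "threshold": float(thr[j])}
    return out


# ---------------------------------------------------------------------------
# gap reports
# ---------------------------------------------------------------------------

@dataclass
class GapReport:
    """Per-group metric values, fairness gaps, and bootstrap CIs for one attribute."""

    attribute: str
    per_group: pd.DataFrame                 # rows (group, label), metric columns
    gaps: pd.DataFrame                      # rows label, metric columns (max-min)
    macro_gaps: dict[str, float]            # metric -> unweighted mean over labels
    n_per_group: dict
    bootstrap: dict | None = None           # metric -> {mean, ci_low, ci_high}


def gap_report(
    scoreset: ScoreSet,
    attribute: str,
    thresholds,
    bootstrap: BootstrapConfig | None = None,
    gap_method: str = "max_min",
) -> GapReport:
    """Full fairness-gap report for one grouping attribute."""
    table = group_metrics(scoreset, attribute, thresholds)
    gap_rows = {}
    for label in scoreset.label_names:
        sub = table[table["label"] == label]
        gap_rows[label] = {
            m: _safe_gap(sub[m].to_numpy(), gap_method) for m in METRIC_NAMES
        }
    gaps = pd.DataFrame(gap_rows).T
    macro = {m: macro_average_gap(gaps[m].to_numpy()) for m in METRIC_NAMES
             if np.isfinite(gaps[m].to_numpy()).any()}
    npg = table.groupby("group")["n"].first().to_dict()

    boot = None
    if bootstrap is not None:
        boot = {}
        for m in METRIC_NAMES:
            def stat(ss, _m=m):
                t = group_metrics(ss, attribute, thresholds)
                g = [_safe_gap(t[t["label"] == l][_m].to_numpy(), gap_method)
                     for l in ss.label_names]
                return macro_average_gap(g)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    boot[m] = bootstrap_ci(stat, scoreset, bootstrap)
                except ValueError:
                    boot[m] = None  # statistic undefined in every replicate
    return GapReport(attribute=attribute, per_group=table, gaps=gaps,
                     macro_gaps=macro, n_per_group=npg, bootstrap=boot)


def _safe_gap(values, method):
    v = np.asarray(values, dtype=float)
    if np.isfinite(v).sum() < 2:
        return float("nan")
    return fairness_gap(v, method)


def macro_ovr_auc(scores: np.ndarray, codes: np.ndarray) -> float:
    """Macro one-vs-rest AUC for a multi-class score matrix (N, C)."""
    scores = np.asarray(scores, dtype=float)
    codes = np.asarray(codes)
    if scores.ndim == 1 or scores.shape[1] == 1:
        return auc(scores.ravel(), codes)
    vals = []
    for c in range(scores.shape[1]):
        y = (codes == c).astype(int)
        if 0 < y.sum() < len(y):
            vals.append(auc(scores[:, c], y))
    if not vals:
        raise ValueError("no class with both positives and negatives")
    return float(np.mean(vals))
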