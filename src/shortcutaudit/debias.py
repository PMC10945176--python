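"""Comparison debiasing methods, each pluggable into the training harness.

Methods, in increasing intrusiveness:

* ``balanced_subsample`` — downsample every group (subject-wise) to the
  minority group's subject count before training.
* ``stratified_train`` — one model per group, routed at inference.
* ``adversarial_train`` — an auxiliary group classifier on the penultimate
  features whose cross-entropy is *maximised* by the main model (gradient
  reversal with weight ``lam``).
* ``distmatch_train`` — a penalty ``gamma * D(scores_A, scores_B)`` between
  per-group score batches, with D either an RBF-kernel MMD^2 (median-heuristic
  bandwidth) or the squared difference of group means.
* ``fairalm_train`` — an augmented-Lagrangian scheme on the constraint
  c = difference of per-group mean BCE risks: the model minimises
  ``task + mu*c + (rho/2)*c^2`` while the multiplier follows ``mu += eta * c``.

Every method at weight 0 (or with a single group) reproduces the baseline
training trajectory under a shared seed, which is the sanity anchor the tests
enforce.  All of these need the demographic attribute at training time; the
geometric-augmentation alternative does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .backend import ModelAdapter, TrainSchedule
from .harness import check_subject_disjoint, train_label_detector
from .synthetic import SyntheticCohort

__all__ = [
    "DebiasConfig",
    "balanced_subsample",
    "stratified_train",
    "adversarial_train",
    "mmd_rbf",
    "distmatch_train",
    "fairalm_train",
    "StratifiedModel",
]

_METHODS = ("baseline", "balanced", "stratified", "adversarial",
            "distmatch_mmd", "distmatch_mean", "fairalm", "augmentation")


@dataclass(frozen=True)
class DebiasConfig:
    method: str = "baseline"
    attribute: str | None = "group"
    adversary_lambda: float = 1.0
    penalty_gamma: float = 1.0
    lagrangian_eta: float = 0.01
    lagrangian_rho: float = 1.0

    def validate(self):
        if self.method not in _METHODS:
            raise ValueError(f"unknown debias method {self.method!r}; choose from {_METHODS}")
        for name in ("adversary_lambda", "penalty_gamma", "lagrangian_rho"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.method not in ("baseline", "augmentation") and self.attribute is None:
            raise ValueError(f"method {self.method!r} requires a demographic attribute")


# ---------------------------------------------------------------------------
# data-level methods
# ---------------------------------------------------------------------------

def balanced_subsample(cohort: SyntheticCohort, attribute: str = "group",
                       seed: int = 0) -> SyntheticCohort:
    """Downsample every group, subject-wise without replacement, to the
    minority group's subject count.  Returns a new cohort."""
    groups = np.asarray(cohort.group)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("balanced subsampling needs at least two groups")
    subj_group = {}
    for sid in np.unique(cohort.subject_id):
        subj_group[sid] = groups[cohort.subject_id == sid][0]
    by_group = {g: [s for s, gg in subj_group.items() if gg == g] for g in uniq}
    for g, subs in by_group.items():
        if len(subs) == 0:
            raise ValueError(f"group {g!r} has no subjects")
    n_min = min(len(s) for s in by_group.values())
    rng = np.random.default_rng(seed)
    keep = []
    for g in uniq:
        subs = np.sort(np.asarray(by_group[g]))
        keep.extend(rng.choice(subs, size=n_min, replace=False))
    mask = np.isin(cohort.subject_id, keep)
    return cohort.subset(np.where(mask)[0])


class StratifiedModel:
    """Per-group adapters with group-routed inference."""

    def __init__(self, adapters: dict):
        self.adapters = adapters

    def predict_scores(self, images, groups) -> np.ndarray:
        groups = np.asarray(groups)
        out = None
        for g in np.unique(groups):
            if g not in self.adapters:
                raise KeyError(f"no model trained for group {g!r}")
            idx = np.where(groups == g)[0]
            scores = self.adapters[g].predict_scores(np.asarray(images)[idx])
            if out is None:
                out = np.zeros((len(groups), scores.shape[1]), dtype=float)
            out[idx] = scores
        return out


def stratified_train(
    train: SyntheticCohort,
    val: SyntheticCohort,
    attribute: str,
    adapter_factory,
    schedule: TrainSchedule,
    policy=None,
) -> StratifiedModel:
    """Train one label detector per group.  ``adapter_factory(group) -> adapter``."""
    check_subject_disjoint(train, val)
    groups = np.unique(train.group)
    bad = []
    for g in groups:
        for split, name in ((train, "train"), (val, "val")):
            sub = split.labels[np.asarray(split.group) == g]
            if len(sub) == 0 or any(len(np.unique(sub[:, j])) < 2 for j in range(sub.shape[1])):
                bad.append((g, name))
    if bad:
        raise ValueError(f"groups failing the class-presence check: {bad}")
    adapters = {}
    for g in groups:
        tr = train.subset(np.where(np.asarray(train.group) == g)[0])
        va = val.subset(np.where(np.asarray(val.group) == g)[0])
        adapters[g] = train_label_detector(tr, va, adapter_factory(g), schedule,
                                           policy=policy)
    return StratifiedModel(adapters)


# ---------------------------------------------------------------------------
# penalty hooks (consumed by ModelAdapter.fit)
# ---------------------------------------------------------------------------

class _AdversarialPenalty:
    """Gradient-reversal adversary: a linear+ReLU+linear group classifier on the
    penultimate features, trained one step per batch; the main model receives
    ``-lam * dCE_adv/dfeats`` so it learns features the adversary cannot use."""

    def __init__(self, feature_dim: int, n_groups: int, lam: float, seed: int = 0,
                 hidden: int = 16, lr: float = 1e-3):
        from .backend import _Adam, _Dense, _ReLU, _softmax  # internal layers

        self.lam = float(lam)
        rng = np.random.default_rng(seed)
        self.l1 = _Dense(feature_dim, hidden, rng=rng)
        self.act = _ReLU()
        self.l2 = _Dense(hidden, n_groups, rng=rng)
        self.opt = _Adam([*self.l1.params, *self.l2.params])
        self.lr = lr
        self.n_groups = n_groups
        self.history = []

    def _forward(self, feats, train):
        h = self.act.forward(self.l1.forward(feats, train=train), train=train)
        return self.l2.forward(h, train=train)

    def adversary_scores(self, feats):
        from .backend import _softmax
        return _softmax(self._forward(feats.astype(np.float32), train=False))

    def on_batch(self, logits, scores, feats, y, groups):
        from .backend import _loss_and_grad
        codes = np.asarray(groups)
        if codes.dtype.kind in "OUS":
            _, codes = np.unique(codes, return_inverse=True)
        codes = codes.astype(int)
        feats32 = feats.astype(np.float32)
        # 1) adversary step on detached features
        z = self._forward(feats32, train=True)
        adv_loss, dz = _loss_and_grad(z, codes, "softmax")
        g = self.l2.backward(dz)
        g = self.act.backward(g)
        self.l1.backward(g)
        self.opt.step([*self.l1.grads, *self.l2.grads], self.lr)
        # 2) reversed gradient for the main model (fresh forward, post-update)
        z = self._forward(feats32, train=True)
        adv_loss, dz = _loss_and_grad(z, codes, "softmax")
        g = self.l2.backward(dz)
        g = self.act.backward(g)
        dfeats = self.l1.backward(g)
        self._last_adv_loss = adv_loss
        return -self.lam * adv_loss, None, (-self.lam * dfeats)

    def on_epoch_end(self, epoch, entry):
        entry["adversary_loss"] = self._last_adv_loss
        self.history.append(self._last_adv_loss)


class _DistMatchPenalty:
    """gamma * D(score_A, score_B) summed over labels and group pairs.

    D is the (biased, differentiable) RBF MMD^2 with median-heuristic bandwidth
    treated as a per-batch constant, or the squared difference of group mean
    scores.  Batches missing a second group contribute zero (counted)."""

    def __init__(self, kind: str, gamma: float):
        if kind not in ("mmd", "mean"):
            raise ValueError(f"distmatch kind must be 'mmd' or 'mean', got {kind!r}")
        self.kind = kind
        self.gamma = float(gamma)
        self.skipped_batches = 0

    def on_batch(self, logits, scores, feats, y, groups):
        codes = np.asarray(groups)
        uniq = np.unique(codes)
        if len(uniq) < 2:
            self.skipped_batches += 1
            return 0.0, None, None
        total = 0.0
        dscores = np.zeros_like(scores)
        for j in range(scores.shape[1]):
            for a in range(len(uniq)):
                for b in range(a + 1, len(uniq)):
                    ia = np.where(codes == uniq[a])[0]
                    ib = np.where(codes == uniq[b])[0]
                    val, da, db = self._pair(scores[ia, j], scores[ib, j])
                    total += val
                    dscores[ia, j] += da
                    dscores[ib, j] += db
        # chain rule through the sigmoid: dpen/dlogit = dpen/ds * s(1-s)
        dlogits = self.gamma * dscores * scores * (1.0 - scores) / logits.shape[0]
        return self.gamma * total, dlogits.astype(np.float32), None

    def _pair(self, sa, sb):
        if self.kind == "mean":
            diff = sa.mean() - sb.mean()
            val = diff**2
            da = np.full_like(sa, 2 * diff / len(sa))
            db = np.full_like(sb, -2 * diff / len(sb))
            return float(val), da, db
        # biased MMD^2 with fixed bandwidth (median heuristic on the batch)
        allv = np.concatenate([sa, sb])
        d = np.abs(allv[:, None] - allv[None, :])
        med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
        sig2 = max(med**2, 1e-12)
        na, nb = len(sa), len(sb)
        kaa = np.exp(-((sa[:, None] - sa[None, :]) ** 2) / (2 * sig2))
        kbb = np.exp(-((sb[:, None] - sb[None, :]) ** 2) / (2 * sig2))
        kab = np.exp(-((sa[:, None] - sb[None, :]) ** 2) / (2 * sig2))
        val = kaa.mean() + kbb.mean() - 2 * kab.mean()
        # gradients of the kernel means (bandwidth held fixed):
        # d exp(-(u-v)^2/2s2)/du = -(u-v)/s2 * k
        daa = (-(sa[:, None] - sa[None, :]) / sig2 * kaa)   # wrt sa_i
        dbb = (-(sb[:, None] - sb[None, :]) / sig2 * kbb)   # wrt sb_i
        dab = (-(sa[:, None] - sb[None, :]) / sig2 * kab)   # wrt sa_i (rows)
        da = 2 * daa.sum(axis=1) / (na * na) - 2 * dab.sum(axis=1) / (na * nb)
        db = 2 * dbb.sum(axis=1) / (nb * nb) + 2 * dab.sum(axis=0) / (na * nb)
        return float(max(val, 0.0)), da, db

    def on_epoch_end(self, epoch, entry):
        entry["distmatch_skipped"] = self.skipped_batches


class _FairALMPenalty:
    """Augmented Lagrangian on c = spread of per-group mean BCE risks."""

    def __init__(self, eta: float, rho: float = 1.0, mu0: float = 0.0):
        if eta < 0:
            raise ValueError("lagrangian step eta must be >= 0")
        self.eta, self.rho = float(eta), float(rho)
        self.mu = float(mu0)
        self._epoch_c = []
        self.constraint_log = []
        self.mu_log = []

    def on_batch(self, logits, scores, feats, y, groups):
        codes = np.asarray(groups)
        uniq = np.unique(codes)
        if len(uniq) < 2:
            return 0.0, None, None
        yf = np.asarray(y, dtype=float).reshape(scores.shape)
        sc = np.clip(scores, 1e-7, 1 - 1e-7)
        per_sample = -(yf * np.log(sc) + (1 - yf) * np.log(1 - sc)).mean(axis=1)
        risks = np.array([per_sample[codes == g].mean() for g in uniq])
        hi, lo = int(np.argmax(risks)), int(np.argmin(risks))
        c = float(risks[hi] - risks[lo])
        self._epoch_c.append(c)
        # d(mu*c + rho/2 c^2)/dlogits through the per-sample BCE of the two
        # extreme groups; dBCE_i/dlogit = (s - y)/L for sample i's own risk
        coeff = self.mu + self.rho * c
        dlogits = np.zeros_like(scores)
        for g, sign in ((uniq[hi], 1.0), (uniq[lo], -1.0)):
            m = codes == g
            dlogits[m] = sign * (sc[m] - yf[m]) / (scores.shape[1] * m.sum())
        val = self.mu * c + 0.5 * self.rho * c * c
        return float(val), (coeff * dlogits).astype(np.float32), None

    def on_epoch_end(self, epoch, entry):
        c_epoch = float(np.mean(self._epoch_c)) if self._epoch_c else 0.0
        self.mu += self.eta * c_epoch
        if abs(self.mu) > 1e6:
            raise RuntimeError(f"FairALM multiplier diverged (mu={self.mu:.3g}); "
                               "reduce eta or rho")
        self.constraint_log.append(c_epoch)
        self.mu_log.append(self.mu)
        entry["constraint"] = c_epoch
        entry["multiplier"] = self.mu
        self._epoch_c = []


# ---------------------------------------------------------------------------
# MMD estimator (also the reference for the penalty)
# ---------------------------------------------------------------------------

def mmd_rbf(a, b, bandwidth: str | float = "median", unbiased: bool = True) -> float:
    """Two-sample MMD^2 with an RBF kernel.

    ``bandwidth='median'`` uses the median pairwise distance over the pooled
    sample.  The unbiased estimator (diagonal terms removed) is clipped at 0;
    samples of size 1 fall back to the biased estimator with a warning.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] == 1 and a.shape[1] > 1:
        a = a.T
    if b.shape[0] == 1 and b.shape[1] > 1:
        b = b.T
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise ValueError("both samples must be non-empty")
    if unbiased and (na < 2 or nb < 2):
        warnings.warn("sample of size 1: falling back to the biased MMD estimator")
        unbiased = False
    pooled = np.vstack([a, b])
    d2 = np.sum((pooled[:, None, :] - pooled[None, :, :]) ** 2, axis=-1)
    if bandwidth == "median":
        dist = np.sqrt(d2[d2 > 0])
        sigma = float(np.median(dist)) if len(dist) else 1.0
    else:
        sigma = float(bandwidth)
    sig2 = max(sigma**2, 1e-12)
    K = np.exp(-d2 / (2 * sig2))
    kaa, kbb, kab = K[:na, :na], K[na:, na:], K[:na, na:]
    if unbiased:
        term_a = (kaa.sum() - np.trace(kaa)) / (na * (na - 1))
        term_b = (kbb.sum() - np.trace(kbb)) / (nb * (nb - 1))
    else:
        term_a = kaa.mean()
        term_b = kbb.mean()
    val = term_a + term_b - 2 * kab.mean()
    return float(max(val, 0.0)) if unbiased else float(val)


# ---------------------------------------------------------------------------
# training wrappers
# ---------------------------------------------------------------------------

def adversarial_train(
    train: SyntheticCohort,
    val: SyntheticCohort,
    adapter: ModelAdapter,
    schedule: TrainSchedule,
    attribute: str = "group",
    lam: float = 1.0,
    policy=None,
    adversary_seed: int = 0,
) -> ModelAdapter:
    """Label detection with a gradient-reversal adversary of weight ``lam``.

    ``lam = 0`` short-circuits to baseline training (identical trajectory)."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    penalty = None
    if lam > 0:
        n_groups = len(np.unique(train.group))
        penalty = _AdversarialPenalty(adapter.feature_dim, n_groups, lam,
                                      seed=adversary_seed)
    fitted = train_label_detector(train, val, adapter, schedule, policy=policy,
                                  penalty=penalty)
    fitted.adversary_ = penalty
    return fitted


def distmatch_train(
    train: SyntheticCohort,
    val: SyntheticCohort,
    adapter: ModelAdapter,
    schedule: TrainSchedule,
    attribute: str = "group",
    penalty: str = "mmd",
    gamma: float = 1.0,
    policy=None,
) -> ModelAdapter:
    """Label detection with a distribution-matching penalty on predicted scores."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    hook = _DistMatchPenalty(penalty, gamma) if gamma > 0 else None
    fitted = train_label_detector(train, val, adapter, schedule, policy=policy,
                                  penalty=hook)
    fitted.distmatch_ = hook
    return fitted


def fairalm_train(
    train: SyntheticCohort,
    val: SyntheticCohort,
    adapter: ModelAdapter,
    schedule: TrainSchedule,
    attribute: str = "group",
    eta: float = 0.01,
    rho: float = 1.0,
    mu0: float = 0.0,
    policy=None,
) -> ModelAdapter:
    """Label detection under the augmented-Lagrangian group-risk constraint."""
    hook = _FairALMPenalty(eta, rho, mu0)
    fitted = train_label_detector(train, val, adapter, schedule, policy=policy,
                                  penalty=hook)
    fitted.fairalm_ = hook
    return fitted
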