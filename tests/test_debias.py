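"""Debiasing comparison methods: data-level operations, penalties, reductions."""

import numpy as np
import pytest

from shortcutaudit import (
    CohortSpec,
    DebiasConfig,
    ShortcutSpec,
    SignalSpec,
    TrainSchedule,
    adversarial_train,
    balanced_subsample,
    distmatch_train,
    fairalm_train,
    generate_cohort,
    mmd_rbf,
    reference_small_cnn,
    split_by_subject,
    stratified_train,
    train_label_detector,
)


@pytest.fixture(scope="module")
def imbalanced_cohort():
    spec = CohortSpec(
        n_subjects=175, images_per_subject=1, image_shape=(32, 32),
        group_names=("big", "mid", "small"), group_proportions=(100 / 175, 50 / 175, 25 / 175),
        label_names=("x",), prevalence_per_group=((0.5,), (0.5,), (0.5,)),
        disease_signal=SignalSpec(contrast=0.3, contrast_sd=0.0, mimic_contrast=0.0, visibility=1.0),
        seed=0)
    return generate_cohort(spec)


@pytest.fixture(scope="module")
def debias_splits():
    spec = CohortSpec(
        n_subjects=120, images_per_subject=1, image_shape=(32, 32),
        group_names=("a", "b"), group_proportions=(0.5, 0.5),
        label_names=("x",), prevalence_per_group=((0.3,), (0.7,)),
        shortcut=ShortcutSpec(leak_rate=1.0),
        disease_signal=SignalSpec(contrast=0.3, contrast_sd=0.0, mimic_contrast=0.0, visibility=1.0),
        seed=1)
    return split_by_subject(generate_cohort(spec), (0.6, 0.2, 0.2), seed=0)


@pytest.fixture(scope="module")
def short_schedule():
    return TrainSchedule(batch_size=16, max_epochs=4, patience=4, seed=0)


def _fresh(seed=0):
    return reference_small_cnn((32, 32), 1, head="sigmoid", channels=(4, 8), seed=seed)


class TestConfig:
    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown debias method"):
            DebiasConfig(method="oversample").validate()

    def test_group_required_for_group_aware_methods(self):
        with pytest.raises(ValueError, match="attribute"):
            DebiasConfig(method="adversarial", attribute=None).validate()
        DebiasConfig(method="augmentation", attribute=None).validate()


class TestBalanced:
    def test_downsamples_to_minority_count(self, imbalanced_cohort):
        c = imbalanced_cohort
        realised = {g: len(np.unique(c.subject_id[np.asarray(c.group) == g]))
                    for g in ("big", "mid", "small")}
        out = balanced_subsample(c, seed=0)
        for g in ("big", "mid", "small"):
            subj = np.unique(out.subject_id[np.asarray(out.group) == g])
            assert len(subj) == min(realised.values())

    def test_already_balanced_keeps_everyone(self, debias_splits):
        tr = debias_splits[0]
        counts = {g: len(np.unique(tr.subject_id[np.asarray(tr.group) == g]))
                  for g in np.unique(tr.group)}
        if len(set(counts.values())) == 1:
            out = balanced_subsample(tr, seed=0)
            assert sorted(out.subject_id.tolist()) == sorted(tr.subject_id.tolist())

    def test_subject_integrity(self, imbalanced_cohort):
        out = balanced_subsample(imbalanced_cohort, seed=3)
        kept = set(out.subject_id.tolist())
        for sid in kept:
            n_in = np.sum(imbalanced_cohort.subject_id == sid)
            assert np.sum(out.subject_id == sid) == n_in

    def test_deterministic(self, imbalanced_cohort):
        a = balanced_subsample(imbalanced_cohort, seed=5)
        b = balanced_subsample(imbalanced_cohort, seed=5)
        assert np.array_equal(a.sample_id, b.sample_id)

    def test_single_group_rejected(self, tiny_cohort):
        only = tiny_cohort.subset(np.where(np.asarray(tiny_cohort.group) == "g0")[0])
        with pytest.raises(ValueError):
            balanced_subsample(only, seed=0)


class TestStratified:
    def test_one_adapter_per_group_and_routing(self, debias_splits, short_schedule):
        tr, va, te = debias_splits
        model = stratified_train(tr, va, "group", lambda g: _fresh(), short_schedule)
        assert set(model.adapters) == {"a", "b"}
        scores = model.predict_scores(te.images, te.group)
        assert scores.shape == (len(te), 1)

    def test_unknown_group_routing_error(self, debias_splits, short_schedule):
        tr, va, te = debias_splits
        model = stratified_train(tr, va, "group", lambda g: _fresh(), short_schedule)
        with pytest.raises(KeyError, match="no model"):
            model.predict_scores(te.images[:2], np.array(["zz", "zz"]))

    def test_class_presence_check(self, short_schedule):
        spec = CohortSpec(n_subjects=40, images_per_subject=1, image_shape=(32, 32),
                          group_names=("a", "b"), group_proportions=(0.5, 0.5),
                          label_names=("x",), prevalence_per_group=((0.0,), (1.0,)),
                          disease_signal=SignalSpec(contrast_sd=0.0, mimic_contrast=0.0, visibility=1.0),
                          seed=2)
        tr, va, _ = split_by_subject(generate_cohort(spec), (0.6, 0.2, 0.2), seed=0)
        with pytest.raises(ValueError, match="class-presence"):
            stratified_train(tr, va, "group", lambda g: _fresh(), short_schedule)


class TestMMD:
    def test_same_sample_near_zero_biased(self, rng):
        a = rng.normal(size=50)
        assert abs(mmd_rbf(a, a, unbiased=False)) < 1e-9

    def test_separated_distributions_large(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(3, 1, 200)
        assert mmd_rbf(a, b) > 0.5

    def test_matches_double_sum_oracle(self, rng):
        a = rng.normal(0, 1, (30, 2))
        b = rng.normal(0.5, 1, (40, 2))
        pooled = np.vstack([a, b])
        d2 = ((pooled[:, None, :] - pooled[None, :, :]) ** 2).sum(-1)
        sigma = np.median(np.sqrt(d2[d2 > 0]))
        k = lambda x, y: np.exp(-((x - y) ** 2).sum() / (2 * sigma**2))
        na, nb = len(a), len(b)
        taa = sum(k(a[i], a[j]) for i in range(na) for j in range(na) if i != j) / (na * (na - 1))
        tbb = sum(k(b[i], b[j]) for i in range(nb) for j in range(nb) if i != j) / (nb * (nb - 1))
        tab = sum(k(x, y) for x in a for y in b) / (na * nb)
        oracle = max(taa + tbb - 2 * tab, 0.0)
        assert mmd_rbf(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_size_one_sample_warns_biased(self, rng):
        with pytest.warns(UserWarning, match="biased"):
            mmd_rbf(rng.normal(size=1), rng.normal(size=20))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mmd_rbf(np.array([]), np.array([1.0]))


class TestWeightZeroReductions:
    """Every penalty at weight 0 reproduces the baseline trajectory exactly."""

    def _baseline(self, splits, sched):
        # shared schedule seed drives shuffling; no external rng so the debias
        # wrappers follow bit-identical batch orderings
        tr, va, _ = splits
        net = train_label_detector(tr, va, _fresh(), sched)
        return net.best_val_loss_

    def test_adversarial_lambda_zero(self, debias_splits, short_schedule):
        tr, va, _ = debias_splits
        base = self._baseline(debias_splits, short_schedule)
        net = adversarial_train(tr, va, _fresh(), short_schedule, lam=0.0)
        assert abs(net.best_val_loss_ - base) < 1e-6

    def test_distmatch_gamma_zero(self, debias_splits, short_schedule):
        tr, va, _ = debias_splits
        base = self._baseline(debias_splits, short_schedule)
        for kind in ("mmd", "mean"):
            net = distmatch_train(tr, va, _fresh(), short_schedule,
                                  penalty=kind, gamma=0.0)
            assert abs(net.best_val_loss_ - base) < 1e-6

    def test_fairalm_zero_multiplier_and_rho(self, debias_splits, short_schedule):
        tr, va, _ = debias_splits
        base = self._baseline(debias_splits, short_schedule)
        net = fairalm_train(tr, va, _fresh(), short_schedule, eta=0.0, rho=0.0)
        assert abs(net.best_val_loss_ - base) < 1e-6


class TestPenaltyMechanics:
    def test_distmatch_penalty_logged_nonnegative(self, debias_splits, short_schedule):
        tr, va, _ = debias_splits
        net = distmatch_train(tr, va, _fresh(), short_schedule, penalty="mmd", gamma=1.0)
        assert all(e.get("penalty", 0.0) >= 0 for e in net.train_log_)

    def test_mean_penalty_shrinks_group_score_difference(self, debias_splits):
        tr, va, te = debias_splits
        sched = TrainSchedule(batch_size=32, max_epochs=8, patience=8, seed=0)
        base = train_label_detector(tr, va, _fresh(), sched,
                                    rng=np.random.default_rng(9))
        pen = distmatch_train(tr, va, _fresh(), sched, penalty="mean", gamma=50.0)

        def gap(net):
            s = net.predict_scores(te.images)[:, 0]
            g = np.asarray(te.group)
            return abs(s[g == "a"].mean() - s[g == "b"].mean())

        assert gap(pen) < gap(base)

    def test_fairalm_multiplier_nondecreasing_under_positive_constraint(
            self, debias_splits, short_schedule):
        tr, va, _ = debias_splits
        net = fairalm_train(tr, va, _fresh(), short_schedule, eta=0.1, rho=1.0)
        hook = net.fairalm_
        mu = np.array(hook.mu_log)
        c = np.array(hook.constraint_log)
        increments = np.diff(np.concatenate([[0.0], mu]))
        assert np.all((increments >= 0) | (c < 0))

    def test_adversarial_logs_adversary_loss(self, debias_splits, short_schedule):
        tr, va, _ = debias_splits
        net = adversarial_train(tr, va, _fresh(), short_schedule, lam=0.5)
        assert all("adversary_loss" in e for e in net.train_log_)

    def test_negative_weights_rejected(self, debias_splits, short_schedule):
        tr, va, _ = debias_splits
        with pytest.raises(ValueError):
            adversarial_train(tr, va, _fresh(), short_schedule, lam=-1)
        with pytest.raises(ValueError):
            distmatch_train(tr, va, _fresh(), short_schedule, gamma=-0.5)
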