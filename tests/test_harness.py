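"""Model backend and harness: adapter contract, schedules, thresholds, TTA, probe."""

import numpy as np
import pytest

from shortcutaudit import (
    AugmentationPolicy,
    BootstrapConfig,
    CohortSpec,
    ScoreSet,
    ShortcutSpec,
    SignalSpec,
    TrainSchedule,
    check_subject_disjoint,
    generate_cohort,
    predict_with_tta,
    preset_schedule,
    reference_small_cnn,
    scoreset_from_cohort,
    select_thresholds,
    split_by_subject,
    task_transfer_probe,
    train_demographic_classifier,
    train_label_detector,
)

IDENTITY_POLICY = AugmentationPolicy(rotation_range=(0, 0), shear_range=(0, 0),
                                     scale_range=(1, 1), fisheye_k=0.0)


@pytest.fixture(scope="module")
def splits(tiny_cohort):
    return split_by_subject(tiny_cohort, (0.6, 0.2, 0.2), seed=0)


@pytest.fixture(scope="module")
def fast_schedule():
    return TrainSchedule(batch_size=16, max_epochs=6, patience=6, seed=0)


@pytest.fixture(scope="module")
def fitted_detector(splits, fast_schedule):
    tr, va, te = splits
    net = reference_small_cnn((32, 32), 1, head="sigmoid", channels=(8, 16), seed=0)
    train_label_detector(tr, va, net, fast_schedule, rng=np.random.default_rng(0))
    return net


class TestAdapterContract:
    def test_softmax_rows_sum_to_one(self, rng):
        net = reference_small_cnn((16, 16), 3, head="softmax", channels=(4, 8), seed=0)
        s = net.predict_scores(rng.random((7, 16, 16)).astype(np.float32))
        assert np.allclose(s.sum(axis=1), 1.0, atol=1e-6)
        assert s.min() >= 0

    def test_sigmoid_scores_in_unit_interval(self, rng):
        net = reference_small_cnn((16, 16), 10, head="sigmoid", channels=(4, 8), seed=0)
        s = net.predict_scores(rng.random((5, 16, 16)).astype(np.float32))
        assert s.shape == (5, 10)
        assert s.min() >= 0 and s.max() <= 1

    def test_feature_dim_constant_across_batch_sizes(self, rng):
        net = reference_small_cnn((16, 16), 2, channels=(4, 8), seed=0)
        x = rng.random((9, 16, 16)).astype(np.float32)
        f_all = net.penultimate_features(x)
        f_small = net.penultimate_features(x, batch_size=2)
        assert f_all.shape == (9, 8)
        assert np.allclose(f_all, f_small)

    def test_input_gradients_match_finite_differences(self, rng):
        net = reference_small_cnn((16, 16), 2, head="sigmoid", channels=(4,), seed=1)
        x = rng.random((3, 16, 16)).astype(np.float32)
        g = net.input_gradients(x, target=0)
        assert g.shape == x.shape
        eps = 1e-3
        xx = x.copy()
        xx[1, 8, 8] += eps
        num = (net.predict_scores(xx)[1, 0] - net.predict_scores(x)[1, 0]) / eps
        assert g[1, 8, 8] == pytest.approx(num, abs=5e-3)

    def test_3d_adapter(self, rng):
        net = reference_small_cnn((16, 16, 16), 2, channels=(4, 8), seed=0)
        x = rng.random((3, 16, 16, 16)).astype(np.float32)
        assert net.predict_scores(x).shape == (3, 2)
        assert net.penultimate_features(x).shape == (3, 8)

    def test_unsupported_shapes_rejected(self):
        with pytest.raises(ValueError):
            reference_small_cnn((16,), 2)
        with pytest.raises(ValueError):
            reference_small_cnn((16, 16), 2, head="linear")


class TestTraining:
    def test_lr_schedule_from_log(self, fitted_detector):
        log = fitted_detector.train_log_
        for entry in log:
            expected = 1e-3 * 0.95 ** (entry["epoch"] // 2)
            assert entry["lr"] == pytest.approx(expected, rel=1e-12)

    def test_early_stopping_honors_caps(self, splits):
        tr, va, _ = splits
        sched = TrainSchedule(batch_size=16, max_epochs=3, patience=2, seed=0)
        net = reference_small_cnn((32, 32), 1, head="sigmoid", channels=(4,), seed=0)
        train_label_detector(tr, va, net, sched, rng=np.random.default_rng(0))
        assert len(net.train_log_) <= 3

    def test_patience_triggers_stop(self, splits):
        # min_delta so large that no epoch ever "improves": stop at patience
        tr, va, _ = splits
        sched = TrainSchedule(batch_size=16, max_epochs=10, patience=2,
                              min_delta=1e9, seed=0)
        net = reference_small_cnn((32, 32), 1, head="sigmoid", channels=(4,), seed=0)
        train_label_detector(tr, va, net, sched, rng=np.random.default_rng(0))
        # the first epoch always improves on the infinite initial best, then the
        # patience counter (2) runs out
        assert len(net.train_log_) == 3

    def test_fixed_seed_identical_first_epoch_loss(self, splits):
        tr, va, _ = splits
        sched = TrainSchedule(batch_size=16, max_epochs=2, patience=2, seed=0)
        losses = []
        for _ in range(2):
            net = reference_small_cnn((32, 32), 1, head="sigmoid", channels=(4,), seed=0)
            train_label_detector(tr, va, net, sched, rng=np.random.default_rng(5))
            losses.append(net.train_log_[0]["train_loss"])
        assert losses[0] == losses[1]

    def test_single_class_demographic_target_rejected(self, tiny_cohort, fast_schedule):
        only = tiny_cohort.subset(np.where(np.asarray(tiny_cohort.group) == "g0")[0])
        tr, va, te = split_by_subject(only, (0.6, 0.2, 0.2), seed=0)
        net = reference_small_cnn((32, 32), 2, head="softmax", channels=(4,), seed=0)
        with pytest.raises(ValueError, match="single class"):
            train_demographic_classifier(tr, va, net, fast_schedule)

    def test_all_zero_label_rejected(self, fast_schedule):
        spec = CohortSpec(n_subjects=30, images_per_subject=1, image_shape=(32, 32),
                          group_names=("a", "b"), group_proportions=(0.5, 0.5),
                          label_names=("never",), prevalence_per_group=((0.0,), (0.0,)),
                          disease_signal=SignalSpec(contrast_sd=0.0, mimic_contrast=0.0, visibility=1.0), seed=0)
        c = generate_cohort(spec)
        tr, va, _ = split_by_subject(c, (0.6, 0.2, 0.2), seed=0)
        net = reference_small_cnn((32, 32), 1, head="sigmoid", channels=(4,), seed=0)
        with pytest.raises(ValueError, match="never"):
            train_label_detector(tr, va, net, fast_schedule)

    def test_subject_leak_guard(self, tiny_cohort, fast_schedule):
        net = reference_small_cnn((32, 32), 1, head="sigmoid", channels=(4,), seed=0)
        with pytest.raises(ValueError, match="leakage"):
            train_label_detector(tiny_cohort, tiny_cohort, net, fast_schedule)
        with pytest.raises(ValueError, match="leakage"):
            check_subject_disjoint(tiny_cohort, tiny_cohort)


class TestThresholds:
    def _oracle(self, scores, truths):
        """Exhaustive grid evaluation with sklearn's weighted F1."""
        from sklearn.metrics import f1_score
        grid = np.round(np.linspace(0, 1, 101), 2)
        f1s = [f1_score(truths, (scores > t).astype(int), average="weighted",
                        zero_division=0) for t in grid]
        return grid, np.asarray(f1s)

    def test_achieves_grid_maximum(self, rng):
        for _ in range(5):
            s = rng.random(60)
            y = rng.integers(0, 2, 60)
            if y.sum() in (0, 60):
                continue
            ts = select_thresholds(s[:, None], y[:, None])
            grid, f1s = self._oracle(s, y)
            chosen = ts.per_label["label_0"]
            achieved = f1s[np.where(grid == np.round(chosen, 2))[0][0]]
            assert achieved == pytest.approx(f1s.max(), abs=1e-12)

    def test_tie_breaks_to_smallest_threshold(self):
        s = np.full(10, 0.7)
        y = np.array([0, 1] * 5)
        ts = select_thresholds(s[:, None], y[:, None])
        assert ts.per_label["label_0"] == 0.0

    def test_perfectly_separable_weighted_f1_is_one(self):
        s = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        ts = select_thresholds(s[:, None], y[:, None])
        t = ts.per_label["label_0"]
        assert 0.2 <= t < 0.8
        from sklearn.metrics import f1_score
        assert f1_score(y, (s > t).astype(int), average="weighted") == 1.0

    def test_no_positives_defaults_to_half_with_warning(self):
        with pytest.warns(UserWarning, match="no positives"):
            ts = select_thresholds(np.array([[0.4], [0.6]]), np.array([[0], [0]]))
        assert ts.per_label["label_0"] == 0.5


class TestTTA:
    def test_identity_policy_reproduces_base_scores(self, fitted_detector, splits):
        _, _, te = splits
        base = fitted_detector.predict_scores(te.images)
        tta = predict_with_tta(fitted_detector, te, IDENTITY_POLICY, 3,
                               rng=np.random.default_rng(0))
        assert np.allclose(tta, base, atol=1e-7)

    def test_tta_is_mean_of_member_scores(self, fitted_detector, splits, rng):
        from shortcutaudit import make_tta_ensemble, preset_policy
        _, _, te = splits
        img = te.images[0]
        pol = preset_policy("cxr")
        members = make_tta_ensemble(img, pol, 3, np.random.default_rng(7))
        expected = fitted_detector.predict_scores(np.stack(members)).mean(axis=0)
        got = predict_with_tta(fitted_detector, img[None], pol, 3,
                               rng=np.random.default_rng(7))
        assert np.allclose(got[0], expected, atol=1e-7)

    def test_tta_variance_not_larger_than_single_draw(self, fitted_detector, splits):
        from shortcutaudit import preset_policy
        from shortcutaudit.harness import distort_images
        _, _, te = splits
        imgs = te.images[:8]
        pol = preset_policy("cxr")
        tta_scores, single_scores = [], []
        for state in range(20):
            tta_scores.append(predict_with_tta(fitted_detector, imgs, pol, 3,
                                               rng=np.random.default_rng(state)))
            one = distort_images(imgs, pol, np.random.default_rng(1000 + state))
            single_scores.append(fitted_detector.predict_scores(one))
        v_tta = np.stack(tta_scores).var(axis=0).mean()
        v_one = np.stack(single_scores).var(axis=0).mean()
        assert v_tta <= v_one


class TestProbe:
    def test_untrained_adapter_on_leakfree_cohort_is_chance(self):
        spec = CohortSpec(
            n_subjects=120, images_per_subject=1, image_shape=(32, 32),
            group_names=("a", "b"), group_proportions=(0.5, 0.5),
            label_names=("x",), prevalence_per_group=((0.5,), (0.5,)),
            shortcut=ShortcutSpec(leak_rate=0.0),
            disease_signal=SignalSpec(contrast_sd=0.0, mimic_contrast=0.0, visibility=1.0), seed=4)
        c = generate_cohort(spec)
        tr, va, te = split_by_subject(c, (0.5, 0.2, 0.3), seed=0)
        net = reference_small_cnn((32, 32), 1, head="sigmoid", channels=(8, 16), seed=0)
        res = task_transfer_probe(net, tr, va, te,
                                  bootstrap=BootstrapConfig(iterations=50),
                                  schedule=TrainSchedule(batch_size=32, max_epochs=20,
                                                         patience=20, seed=0))
        assert 0.35 <= res.auc <= 0.65

    def test_backbone_features_unchanged_by_probe(self, fitted_detector, splits):
        tr, va, te = splits
        before = fitted_detector.penultimate_features(te.images)
        task_transfer_probe(fitted_detector, tr, va, te,
                            bootstrap=BootstrapConfig(iterations=20))
        after = fitted_detector.penultimate_features(te.images)
        assert np.array_equal(before, after)

    def test_probe_reads_group_from_demographic_backbone(self, splits):
        # a backbone trained to classify the group must expose it to the probe
        tr, va, te = splits
        net = reference_small_cnn((32, 32), 1, head="sigmoid", channels=(8, 16), seed=0)
        sched = TrainSchedule(batch_size=8, initial_lr=0.01, max_epochs=30,
                              patience=30, seed=0)
        train_demographic_classifier(tr, va, net, sched,
                                     rng=np.random.default_rng(0))
        res = task_transfer_probe(net, tr, va, te,
                                  bootstrap=BootstrapConfig(iterations=30))
        assert res.auc > 0.8

    def test_freeze_returns_independent_head(self, fitted_detector):
        frozen = fitted_detector.freeze_backbone(n_outputs=3, head="softmax")
        assert frozen.frozen and not fitted_detector.frozen
        assert frozen.head_layer.W.shape[0] == 3


def test_scoreset_from_cohort_roundtrip(tiny_cohort):
    scores = np.random.default_rng(0).random((len(tiny_cohort), 1))
    ss = scoreset_from_cohort(tiny_cohort, scores)
    assert isinstance(ss, ScoreSet)
    assert np.array_equal(ss.truths, tiny_cohort.labels)
    assert list(ss.groups["group"]) == list(tiny_cohort.group)


def test_preset_schedules_match_protocol():
    cxr = preset_schedule("cxr")
    assert (cxr.batch_size, cxr.patience, cxr.max_epochs) == (128, 4, 15)
    assert cxr.initial_lr == 1e-3 and cxr.lr_decay == 0.95 and cxr.decay_every == 2
    mri = preset_schedule("mri")
    assert (mri.batch_size, mri.patience, mri.max_epochs) == (16, 10, 80)
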