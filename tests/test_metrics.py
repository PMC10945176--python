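"""Metric layer: scalar metrics vs brute-force oracles, gaps, bootstrap."""

import warnings

import numpy as np
import pytest
from scipy import stats

from shortcutaudit import (
    BootstrapConfig,
    ScoreSet,
    auc,
    bce,
    bootstrap_ci,
    ece,
    error_rate,
    fairness_gap,
    gap_report,
    group_metrics,
    macro_average_gap,
    macro_ovr_auc,
    precision,
    roc_with_cutoff,
)


def brute_force_auc(scores, truths):
    """Exhaustive pair enumeration: concordant + half ties over n1*n0 pairs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truths)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def make_scoreset(scores, truths, groups=None, label="l"):
    scores = np.asarray(scores, dtype=float)[:, None]
    truths = np.asarray(truths)[:, None]
    g = {"attr": np.asarray(groups)} if groups is not None else {}
    return ScoreSet(sample_id=np.arange(len(scores)), scores=scores, truths=truths,
                    label_names=(label,), groups=g)


class TestAUC:
    def test_perfect_and_reversed(self):
        s = [0.9, 0.8, 0.2, 0.1]
        assert auc(s, [1, 1, 0, 0]) == 1.0
        assert auc(s, [0, 0, 1, 1]) == 0.0

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(5):
            s = rng.integers(0, 10, size=50) / 10.0  # ties likely
            y = rng.integers(0, 2, size=50)
            if 0 < y.sum() < 50:
                assert auc(s, y) == pytest.approx(brute_force_auc(s, y), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        s, y = rng.random(100), rng.integers(0, 2, 100)
        assert auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        s, y = rng.random(60), rng.integers(0, 2, 60)
        assert auc(s, y) == pytest.approx(auc(np.exp(3 * s), y), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([0.1, 0.9], [1, 1])


class TestBCE:
    def test_exact_scores_near_zero(self):
        y = np.array([0, 1, 1, 0])
        assert bce(y.astype(float), y) <= 1.2e-7

    def test_half_scores_log2(self):
        assert bce([0.5] * 8, [0, 1] * 4) == pytest.approx(np.log(2), abs=1e-12)

    def test_term_by_term_oracle(self, rng):
        s, y = rng.random(20), rng.integers(0, 2, 20)
        sc = np.clip(s, 1e-7, 1 - 1e-7)
        manual = -np.mean([yi * np.log(si) + (1 - yi) * np.log(1 - si)
                           for si, yi in zip(sc, y)])
        assert bce(s, y) == pytest.approx(manual, abs=1e-12)


class TestECE:
    def test_perfectly_confident_and_right(self):
        assert ece(np.ones(10), np.ones(10)) == 0.0

    def test_confident_and_wrong_closed_form(self):
        assert ece(np.full(10, 0.9), np.zeros(10)) == pytest.approx(0.9, abs=1e-12)

    def test_bin_summation_oracle(self, rng):
        s, y = rng.random(200), rng.integers(0, 2, 200)
        n_bins = 10
        idx = np.clip(np.ceil(s * n_bins).astype(int) - 1, 0, n_bins - 1)
        expected = sum(
            (np.sum(idx == b) / 200) * abs(y[idx == b].mean() - s[idx == b].mean())
            for b in range(n_bins) if np.any(idx == b))
        assert ece(s, y) == pytest.approx(expected, abs=1e-12)

    def test_calibrated_by_construction_limit(self):
        rng = np.random.default_rng(2021)
        s = rng.random(100_000)
        y = (rng.random(100_000) < s).astype(int)
        assert ece(s, y) < 0.02


class TestThresholded:
    def test_perfect_at_half(self):
        s, y = np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0])
        assert error_rate(s, y, 0.5) == 0.0
        assert precision(s, y, 0.5) == 1.0

    def test_confusion_matrix_oracle(self):
        # TP=3, FP=1, FN=2, TN=4 at threshold 0.5
        s = np.array([0.9, 0.8, 0.7, 0.6, 0.3, 0.2, 0.1, 0.15, 0.05, 0.25])
        y = np.array([1, 1, 1, 0, 1, 1, 0, 0, 0, 0])
        assert error_rate(s, y, 0.5) == pytest.approx(0.3)
        assert precision(s, y, 0.5) == pytest.approx(0.75)

    def test_threshold_zero_precision_is_prevalence(self, rng):
        s = rng.random(40) * 0.98 + 0.01
        y = rng.integers(0, 2, 40)
        assert precision(s, y, 0.0) == pytest.approx(y.mean())

    def test_undefined_precision_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = precision(np.array([0.1, 0.2]), np.array([1, 0]), 0.9)
        assert np.isnan(out)


class TestGroups:
    def test_identical_groups_equal_metrics(self, rng):
        s = np.tile(rng.random(50), 2)
        y = np.tile(rng.integers(0, 2, 50), 2)
        g = np.repeat(["a", "b"], 50)
        table = group_metrics(make_scoreset(s, y, g), "attr", [0.5])
        a, b = table[table.group == "a"], table[table.group == "b"]
        for m in ("auc", "bce", "ece", "error_rate", "precision"):
            assert a[m].iloc[0] == pytest.approx(b[m].iloc[0], abs=1e-12)

    def test_per_group_auc_matches_oracle(self, rng):
        s, y = rng.random(80), rng.integers(0, 2, 80)
        g = np.repeat(["a", "b"], 40)
        table = group_metrics(make_scoreset(s, y, g), "attr", 0.5)
        for name, m in (("a", slice(0, 40)), ("b", slice(40, 80))):
            row = table[table.group == name]
            assert row["auc"].iloc[0] == pytest.approx(
                brute_force_auc(s[m], y[m]), abs=1e-12)

    def test_one_class_group_auc_omitted(self):
        s = np.array([0.2, 0.4, 0.6, 0.8])
        y = np.array([1, 1, 0, 1])
        g = np.array(["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="one truth class"):
            table = group_metrics(make_scoreset(s, y, g), "attr", 0.5)
        assert np.isnan(table[table.group == "a"]["auc"].iloc[0])


class TestGaps:
    def test_equal_values_zero_gap(self):
        assert fairness_gap([0.8, 0.8, 0.8]) == 0.0

    def test_max_min_arithmetic(self):
        assert fairness_gap([0.937, 0.954, 0.950]) == pytest.approx(0.017, abs=1e-12)

    def test_order_and_duplicate_invariance(self):
        vals = [0.7, 0.9, 0.8]
        g = fairness_gap(vals)
        assert fairness_gap(vals[::-1]) == g
        assert fairness_gap(vals + [0.9]) == g

    def test_needs_two_finite(self):
        with pytest.raises(ValueError):
            fairness_gap([0.5, float("nan")])

    def test_mean_pairwise_alternative(self):
        assert fairness_gap([0.0, 1.0], method="mean_pairwise") == 1.0

    def test_macro_average(self):
        assert macro_average_gap([0.1, 0.3]) == pytest.approx(0.2)


class TestBootstrap:
    def test_constant_statistic_zero_width(self, rng):
        ss = make_scoreset(np.full(30, 0.5), rng.integers(0, 2, 30))
        out = bootstrap_ci(lambda s: 1.23, ss, BootstrapConfig(iterations=50))
        assert out["ci_low"] == out["ci_high"] == out["mean"] == 1.23

    def test_seed_determinism(self, rng):
        ss = make_scoreset(rng.random(100), rng.integers(0, 2, 100))
        cfg = BootstrapConfig(iterations=200, seed=2021)
        stat = lambda s: float(s.scores.mean())
        assert bootstrap_ci(stat, ss, cfg) == bootstrap_ci(stat, ss, cfg)

    def test_width_matches_normal_theory(self):
        rng = np.random.default_rng(2021)
        vals = rng.random(200)
        ss = make_scoreset(vals, rng.integers(0, 2, 200))
        out = bootstrap_ci(lambda s: float(s.scores.mean()), ss,
                           BootstrapConfig(iterations=1000, seed=2021))
        width = out["ci_high"] - out["ci_low"]
        analytic = 2 * 1.96 * vals.std(ddof=1) / np.sqrt(200)
        assert abs(width - analytic) / analytic < 0.2

    def test_mean_converges_with_iterations(self, rng):
        vals = rng.random(150)
        ss = make_scoreset(vals, rng.integers(0, 2, 150))
        point = float(vals.mean())
        errs = []
        for b in (10, 100, 1000):
            out = bootstrap_ci(lambda s: float(s.scores.mean()), ss,
                               BootstrapConfig(iterations=b, seed=1))
            errs.append(abs(out["mean"] - point))
        assert errs[2] < errs[0] + 0.02 and errs[2] < 0.01

    def test_subject_unit_resampling(self, rng):
        ss = ScoreSet(sample_id=np.arange(40), scores=rng.random((40, 1)),
                      truths=rng.integers(0, 2, (40, 1)), label_names=("l",),
                      subject_id=np.repeat(np.arange(10), 4))
        out = bootstrap_ci(lambda s: float(s.scores.mean()), ss,
                           BootstrapConfig(iterations=50, unit="subject"))
        assert out["n_replicates"] == 50


class TestROC:
    def test_perfect_cutoff_point(self):
        ss = make_scoreset([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0],
                           ["a", "a", "a", "a"])
        out = roc_with_cutoff(ss, "attr", 0.5)
        assert out["a"]["l"]["cutoff_point"] == (0.0, 1.0)

    def test_threshold_zero_is_corner(self, rng):
        s = rng.random(30) * 0.9 + 0.05
        ss = make_scoreset(s, rng.integers(0, 2, 30), ["a"] * 30)
        out = roc_with_cutoff(ss, "attr", 0.0)
        assert out["a"]["l"]["cutoff_point"] == (1.0, 1.0)

    def test_trapezoid_area_equals_auc(self, rng):
        s, y = rng.random(60), rng.integers(0, 2, 60)
        ss = make_scoreset(s, y, ["a"] * 60)
        out = roc_with_cutoff(ss, "attr", 0.5)
        area = np.trapezoid(out["a"]["l"]["tpr"], out["a"]["l"]["fpr"])
        assert area == pytest.approx(auc(s, y), abs=1e-9)


def test_gap_report_end_to_end(rng):
    s = np.concatenate([rng.random(60), rng.random(60) * 0.5])
    y = rng.integers(0, 2, 120)
    ss = make_scoreset(s, y, np.repeat(["a", "b"], 60))
    rep = gap_report(ss, "attr", 0.4, bootstrap=BootstrapConfig(iterations=50))
    assert set(rep.macro_gaps) <= {"auc", "bce", "ece", "error_rate", "precision"}
    for m, b in rep.bootstrap.items():
        if b is not None:
            assert b["ci_low"] <= b["mean"] <= b["ci_high"]
    assert all(g >= 0 for g in rep.macro_gaps.values())


def test_macro_ovr_auc_multiclass(rng):
    scores = rng.random((90, 3))
    codes = rng.integers(0, 3, 90)
    expected = np.mean([auc(scores[:, c], (codes == c).astype(int)) for c in range(3)])
    assert macro_ovr_auc(scores, codes) == pytest.approx(expected, abs=1e-12)
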