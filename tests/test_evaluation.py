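"""Nested CV harness, metrics, voting, per-minute error rates."""

import numpy as np
import pytest

from fecgsqi.errors import ConfigError
from fecgsqi.evaluation import (
    CVResult,
    FoldSpec,
    error_rate_per_minute,
    majority_vote,
    metrics,
    nested_cv,
    stratified_folds,
)


class TestStratifiedFolds:
    def test_exact_divisibility(self):
        y = np.array([1] * 20 + [0] * 20)
        folds = stratified_folds(y, 10, seed=0)
        for f in range(10):
            assert np.sum(y[folds == f] == 1) == 2
            assert np.sum(y[folds == f] == 0) == 2

    def test_remainder_distribution(self):
        y = np.array([1] * 21 + [0] * 19)
        folds = stratified_folds(y, 10, seed=0)
        for f in range(10):
            assert np.sum(y[folds == f] == 1) in (2, 3)
            assert np.sum(y[folds == f] == 0) in (1, 2)

    def test_partition_property(self):
        y = np.array([0, 1] * 25)
        folds = stratified_folds(y, 5, seed=1)
        assert folds.size == 50
        assert set(folds) == set(range(5))

    def test_k_too_large_rejected(self):
        with pytest.raises(ConfigError):
            stratified_folds(np.array([0, 1] * 20), 50, seed=0)

    def test_recording_grouping_no_split(self):
        y = np.repeat([1, 0, 1, 0, 1, 0], 8)
        groups = np.repeat(np.arange(6), 8)
        folds = stratified_folds(y, 3, seed=0, grouping="recording", groups=groups)
        for g in np.unique(groups):
            assert np.unique(folds[groups == g]).size == 1


class TestMetrics:
    def test_perfect_separation(self):
        m = metrics(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]))
        assert all(m[k] == 1.0 for k in ("accuracy", "precision", "recall", "f1", "auc"))

    def test_worked_confusion_arithmetic(self):
        """41 TP, 49 TN, 14 FP, 4 FN -> accuracy 0.833, precision 0.745,
        recall 0.911 (the worked clinician-subset example)."""
        scores = np.concatenate([np.ones(41), np.zeros(49), np.ones(14), np.zeros(4)])
        labels = np.concatenate([np.ones(41), np.zeros(49), np.zeros(14), np.ones(4)]).astype(int)
        m = metrics(scores, labels)
        assert m["tp"] == 41 and m["tn"] == 49 and m["fp"] == 14 and m["fn"] == 4
        assert m["accuracy"] == pytest.approx((41 + 49) / 108, abs=1e-3)
        assert m["precision"] == pytest.approx(41 / 55, abs=1e-3)
        assert m["recall"] == pytest.approx(41 / 45, abs=1e-3)

    def test_constant_score_all_positive(self):
        labels = np.array([1, 0, 1, 0, 1])
        m = metrics(np.full(5, 0.7), labels)
        assert m["recall"] == 1.0
        assert m["precision"] == pytest.approx(3 / 5)

    def test_auc_matches_brute_force_pair_counting(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = rng.uniform(size=n)
            pos, neg = s[y == 1], s[y == 0]
            pairs = [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
            assert metrics(s, y)["auc"] == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigError):
            metrics(np.array([0.1, 0.9]), np.array([1, 1]))


class TestErrorRatePerMinute:
    def test_event_every_84_55_seconds(self):
        """One false event per 84.55 s equals 0.71 per minute."""
        total_minutes = 84.55 / 60.0
        fp_rate, fn_rate = error_rate_per_minute(1, 1, total_minutes)
        assert round(fp_rate, 2) == 0.71
        assert round(fn_rate, 2) == 0.71

    def test_zero_events(self):
        assert error_rate_per_minute(0, 0, 5.0) == (0.0, 0.0)

    def test_simple_rate(self):
        assert error_rate_per_minute(6, 3, 3.0) == (2.0, 1.0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ConfigError):
            error_rate_per_minute(1, 1, 0.0)


class TestMajorityVote:
    def test_strict_majority(self):
        assert majority_vote([1, 1, 0]) == 1
        assert majority_vote([0, 0, 1]) == 0

    def test_tie_goes_to_bad(self):
        assert majority_vote([1, 0]) == 0

    def test_flips_absorbed(self):
        labels = [1] * 22 + [0] * 2
        assert majority_vote(labels) == 1

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            majority_vote([])


@pytest.fixture(scope="module")
def separable_features():
    rng = np.random.default_rng(1)
    x = np.vstack([rng.standard_normal((60, 45)), rng.standard_normal((60, 45)) + 2.0])
    y = np.concatenate([np.zeros(60, dtype=int), np.ones(60, dtype=int)])
    perm = rng.permutation(120)
    return x[perm], y[perm]


class TestNestedCv:

    def test_record_bookkeeping(self, separable_features):
        from fecgsqi.benchmark import GridSpec

        x, y = separable_features
        spec = FoldSpec(outer_k=3, inner_k=2, repetitions=2, seed=0)
        res = nested_cv(x, y, "nb", spec, grid=GridSpec("nb", {"var_smoothing": [1e-9]}))
        assert len(res.records) == 6  # 2 repetitions x 3 outer folds
        agg = res.aggregate()
        assert agg["tp"] + agg["fp"] + agg["tn"] + agg["fn"] == 2 * 120

    def test_aggregate_matches_record_mean(self, separable_features):
        from fecgsqi.benchmark import GridSpec

        x, y = separable_features
        res = nested_cv(x, y, "nb", FoldSpec(outer_k=3, inner_k=2, seed=1), grid=GridSpec("nb", {"var_smoothing": [1e-9]}))
        agg = res.aggregate()
        assert agg["auc"]["mean"] == pytest.approx(np.mean([r["auc"] for r in res.records]))
        assert agg["auc"]["std"] == pytest.approx(np.std([r["auc"] for r in res.records], ddof=1))

    def test_shuffled_labels_near_chance(self):
        # larger null sample + repetitions so the chance band is tight
        from fecgsqi.benchmark import GridSpec

        rng = np.random.default_rng(1)
        x = rng.standard_normal((300, 45))
        y_shuffled = rng.integers(0, 2, 300)
        res = nested_cv(
            x, y_shuffled, "nb",
            FoldSpec(outer_k=3, inner_k=2, repetitions=2, seed=2),
            grid=GridSpec("nb", {"var_smoothing": [1e-9]}),
        )
        assert 0.4 <= res.aggregate()["auc"]["mean"] <= 0.6

    def test_recording_grouping_no_leakage(self):
        rng = np.random.default_rng(5)
        groups = np.repeat(np.arange(12), 4)
        y = np.repeat(np.arange(12) % 2, 4)
        x = rng.standard_normal((48, 45)) + y[:, None]
        from fecgsqi.benchmark import GridSpec

        spec = FoldSpec(outer_k=3, inner_k=2, grouping="recording", seed=0)
        res = nested_cv(x, y, "nb", spec, groups=groups, grid=GridSpec("nb", {"var_smoothing": [1e-9]}))
        assert len(res.records) == 3
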