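import math

import numpy as np
import pytest

import enhmom as em


def random_counts(rng):
    tp, tn, fp, fn = (int(v) for v in rng.integers(0, 200, size=4))
    return em.ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


class TestMetrics:
    def test_balanced_random_prediction_is_chance(self):
        m = em.compute_metrics(em.ConfusionCounts(tp=25, tn=25, fp=25, fn=25))
        assert m.acc == 0.5
        assert m.mcc == 0.0

    def test_no_missed_positives_gives_perfect_sensitivity(self):
        m = em.compute_metrics(em.ConfusionCounts(tp=10, tn=5, fp=3, fn=0))
        assert m.sn == 1.0

    def test_everything_wrong_gives_negative_one_mcc(self):
        m = em.compute_metrics(em.ConfusionCounts(tp=0, tn=0, fp=7, fn=9))
        assert m.acc == 0.0
        assert m.mcc == -1.0

    def test_everything_right_gives_one(self):
        m = em.compute_metrics(em.ConfusionCounts(tp=7, tn=9, fp=0, fn=0))
        assert m.acc == 1.0
        assert m.mcc == 1.0

    def test_zero_denominators_yield_nan_except_mcc(self):
        m = em.compute_metrics(em.ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert math.isnan(m.sn)  # no positives at all
        assert m.sp == 1.0
        assert m.mcc == 0.0  # 0/0 convention

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            em.compute_metrics(em.ConfusionCounts(tp=0, tn=0, fp=0, fn=0))

    def test_adding_a_correct_prediction_never_decreases_accuracy(self, rng):
        for _ in range(50):
            c = random_counts(rng)
            if c.total == 0:
                continue
            better = em.ConfusionCounts(c.tp + 1, c.tn, c.fp, c.fn)
            assert (
                em.compute_metrics(better).acc >= em.compute_metrics(c).acc
            )


class TestChouFormulation:
    def test_conversion_example(self):
        chou = em.chou_convert(em.ConfusionCounts(tp=10, tn=4, fp=3, fn=2))
        assert chou.y_plus == 12
        assert chou.y_plus_as_minus == 2

    def test_round_trip_exact_on_random_counts(self, rng):
        for _ in range(1000):
            c = random_counts(rng)
            assert em.chou_invert(em.chou_convert(c)) == c

    def test_formulations_agree_to_1e12(self, rng):
        checked = 0
        for _ in range(1000):
            c = random_counts(rng)
            if c.total == 0:
                continue
            conv = em.compute_metrics(c)
            chou = em.compute_metrics_chou(em.chou_convert(c))
            for a, b in zip(conv.as_dict().values(), chou.as_dict().values()):
                if math.isnan(a) or math.isnan(b):
                    assert math.isnan(a) == math.isnan(b)
                else:
                    assert a == pytest.approx(b, abs=1e-12)
                    checked += 1
        assert checked > 1000  # plenty of defined comparisons happened


def brute_force_auc(y_true, scores):
    """Mann-Whitney pair statistic: P(score+ > score-) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, y_true) if y == 1]
    neg = [s for s, y in zip(scores, y_true) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestScoreCurves:
    def test_perfect_ranker(self):
        out = em.score_curves([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert out["auc"] == 1.0
        assert out["aupr"] == 1.0

    def test_constant_scorer_is_chance(self):
        out = em.score_curves([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert out["auc"] == 0.5

    def test_frozen_three_point_example(self):
        # pairs: (0.9 vs 0.8) win, (0.3 vs 0.8) loss -> AUC = 0.5
        out = em.score_curves([1, 0, 1], [0.9, 0.8, 0.3])
        assert out["auc"] == 0.5

    def test_auc_matches_pair_statistic_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 50))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.random(n), 2)  # coarse grid to exercise ties
            out = em.score_curves(y, s)
            assert out["auc"] == pytest.approx(brute_force_auc(y, s), abs=1e-12)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            em.score_curves([1, 1, 1], [0.5, 0.6, 0.7])

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            em.score_curves([1, 0], [1.5, -0.2])


class TestCrossValidate:
    def test_every_row_predicted_once_with_balanced_folds(self, small_table):
        result = em.cross_validate(small_table, 1, 5, seed=1)
        n = len(small_table)
        assert result.pooled_counts.total == n
        fold_sizes = np.bincount(result.fold_assignment)
        assert fold_sizes.min() >= n // 5 - 1
        assert fold_sizes.max() <= n // 5 + 1

    def test_jackknife_is_leave_one_out(self, small_table):
        keep = list(range(15)) + list(range(60, 75))  # 15 enhancers + 15 non
        sub = em.FeatureTable(
            small_table.data.iloc[keep],
            [small_table.layer1[i] for i in keep],
            [small_table.layer2[i] for i in keep],
            small_table.provenance,
        )
        result = em.cross_validate(sub, 1, "loo", seed=1)
        assert len(np.unique(result.fold_assignment)) == 30
        assert result.pooled_counts.total == 30

    def test_separable_fixture_reaches_high_pooled_accuracy(self, small_table):
        result = em.cross_validate(small_table, 1, 5, seed=1)
        assert result.pooled.acc >= 0.9

    def test_reproducible_given_seed(self, small_table):
        a = em.cross_validate(small_table, 1, 5, seed=4)
        b = em.cross_validate(small_table, 1, 5, seed=4)
        assert (a.scores == b.scores).all()
        assert a.pooled == b.pooled

    def test_k_exceeding_smallest_class_rejected(self, small_table):
        with pytest.raises(ValueError, match="smallest class"):
            em.cross_validate(small_table, 1, 100, seed=1)

    def test_per_fold_metrics_reported(self, small_table):
        result = em.cross_validate(small_table, 1, 5, seed=1)
        assert len(result.per_fold) == 5
        assert all(0 <= m.acc <= 1 for m in result.per_fold)


def test_percent_formatting_is_reporting_only():
    m = em.Metrics(sn=0.8490, sp=0.8821, acc=0.86563, mcc=0.73190, auc=0.93)
    formatted = em.metrics_percent(m)
    assert formatted["acc"] == 86.56
    assert formatted["mcc"] == 0.7319
    assert formatted["auc"] == 0.93
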