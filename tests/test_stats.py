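"""Patient-level statistics: ASPECTS scoring, rank correlations, DeLong."""

import numpy as np
import pytest

from ctaspects import (
    auc,
    compare_dependent_correlations,
    delong_test,
    outcome_auc,
    spearman_ci,
    threshold_aspects,
)
from ctaspects.stats import delong_auc_variance


class TestThresholdAspects:
    @pytest.mark.parametrize("n_pred,expected", [(0, 10), (4, 6), (10, 0)])
    def test_ten_minus_predicted_count(self, n_pred, expected):
        preds = [True] * n_pred + [False] * (10 - n_pred)
        assert threshold_aspects(preds) == expected

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="10 region"):
            threshold_aspects([True] * 9)


class TestSpearmanCI:
    def test_monotone_increasing_gives_one(self):
        x = np.arange(20.0)
        res = spearman_ci(x, x**3 + 1, bootstrap_reps=200, seed=0)
        assert res.r_s == pytest.approx(1.0)

    def test_monotone_decreasing_gives_minus_one(self):
        x = np.arange(20.0)
        res = spearman_ci(x, -x, bootstrap_reps=200, seed=0)
        assert res.r_s == pytest.approx(-1.0)

    def test_ci_brackets_the_estimate(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=150)
        y = 0.5 * x + rng.normal(size=150)
        res = spearman_ci(x, y, bootstrap_reps=2000, seed=2)
        assert res.ci_low <= res.r_s <= res.ci_high
        assert res.n == 150

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=80)
        y = x + rng.normal(size=80)
        a = spearman_ci(x, y, 100, seed=0).r_s
        b = spearman_ci(np.exp(x), y**3, 100, seed=0).r_s
        assert a == pytest.approx(b, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_ci(np.ones(10), np.arange(10.0), 100, seed=0)


class TestDependentCorrelationComparison:
    def test_identical_predictors_give_p_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        assert compare_dependent_correlations(x, x, y, 1000, seed=0) == 1.0

    def test_grossly_different_predictors_rejected(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=200)
        good = y + 0.1 * rng.normal(size=200)  # near-perfect predictor
        junk = rng.normal(size=200)  # independent noise
        p = compare_dependent_correlations(good, junk, y, 1000, seed=1)
        assert p < 0.01

    def test_low_rep_count_warns(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=(2, 30))
        with pytest.warns(UserWarning, match="1000"):
            compare_dependent_correlations(x, x + y, y, 200, seed=0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            compare_dependent_correlations(
                np.arange(5.0), np.arange(5.0), np.arange(5.0), 1000
            )


class TestDeLong:
    def test_identical_scores_give_zero_delta_and_p_one(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=40)
        y = rng.random(40) < 0.5
        res = delong_test(s, s.copy(), y)
        assert res.delta == 0.0 and res.p_value == 1.0

    def test_matches_reference_implementation(self):
        """Frozen oracle: R pROC roc.test(method='delong') on this instance."""
        y = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        a = [0.90, 0.55, 0.70, 0.80, 0.60, 0.35, 0.65, 0.50, 0.75, 0.40]
        b = [0.60, 0.85, 0.75, 0.50, 0.55, 0.45, 0.70, 0.30, 0.65, 0.80]
        res = delong_test(a, b, y)
        assert res.auc_a == pytest.approx(0.8333333333, abs=1e-9)
        assert res.auc_b == pytest.approx(0.6666666667, abs=1e-9)
        assert res.z == pytest.approx(0.5725983343, abs=1e-9)
        assert res.p_value == pytest.approx(0.5669166878, abs=1e-9)
        assert res.ci_a[0] == pytest.approx(0.5504368998, abs=1e-9)
        assert res.ci_b[0] == pytest.approx(0.2824641002, abs=1e-9)

    def test_placement_auc_equals_mann_whitney_auc(self):
        # the DeLong placement mean and the rank-based AUC are the same
        # statistic under opposite orientations
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = rng.integers(8, 60)
            s = rng.normal(size=n) + rng.integers(0, 2)  # allow ties sometimes
            s = np.round(s, 1)
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            a_delong, _ = delong_auc_variance(s, y)
            assert a_delong == pytest.approx(auc(-s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            delong_test([1.0, 2.0], [2.0, 1.0], [1, 1])


class TestOutcomeAUC:
    def test_perfectly_discriminating_aspects(self):
        aspects = [0, 0, 0, 10, 10, 10]
        poor = [1, 1, 1, 0, 0, 0]
        a, ci = outcome_auc(aspects, poor)
        assert a == 1.0
        assert ci[1] == 1.0

    def test_constant_aspects_give_chance(self):
        a, _ = outcome_auc([5] * 10, [1, 0] * 5)
        assert a == 0.5

    def test_independent_aspects_near_chance(self):
        rng = np.random.default_rng(9)
        aspects = rng.integers(0, 11, size=500)
        poor = rng.random(500) < 0.5
        a, ci = outcome_auc(aspects, poor)
        assert a == pytest.approx(0.5, abs=0.07)
        assert ci[0] <= a <= ci[1]

    def test_low_aspects_means_high_risk_orientation(self):
        # mostly-low ASPECTS in poor-outcome patients must give AUC > 0.5
        aspects = [2, 3, 4, 8, 9, 10, 3, 9]
        poor = [1, 1, 1, 0, 0, 0, 1, 0]
        a, _ = outcome_auc(aspects, poor)
        assert a > 0.9
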