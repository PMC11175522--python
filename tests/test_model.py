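"""Youden cut points, AUC and cross-validation of the threshold model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctaspects import (
    CutPointModel,
    Region,
    TabularSimSpec,
    auc,
    cross_validate,
    fit,
    predict_region,
    region_metrics,
    simulate_tabular,
    youden_cutpoint,
)
from ctaspects.model import SingleClassError


def brute_force_youden(scores, labels):
    """Independent oracle: scan every candidate boundary with plain loops,
    scoring J in exact rational arithmetic."""
    from fractions import Fraction

    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    distinct = sorted(set(scores))
    candidates = [distinct[0]]
    candidates += [(a + b) / 2 for a, b in zip(distinct, distinct[1:])]
    candidates += [float("inf")]
    best_t, best_j = None, None
    for t in candidates:
        tp = sum(1 for s, y in zip(scores, labels) if y and s < t)
        tn = sum(1 for s, y in zip(scores, labels) if not y and s >= t)
        j = Fraction(tp, n_pos) + Fraction(tn, n_neg) - 1
        if best_j is None or j > best_j:  # strict: keeps the smallest t on ties
            best_t, best_j = t, j
    return best_t, float(best_j)


class TestYoudenCutpoint:
    def test_separable_example_midpoint(self):
        t, j = youden_cutpoint(
            [0.80, 0.85, 0.90, 0.93, 0.95, 0.97], [1, 1, 1, 0, 0, 0]
        )
        assert t == pytest.approx(0.915)
        assert j == pytest.approx(1.0)

    def test_ties_in_j_break_to_smallest_threshold(self):
        # labels independent of scores: J = 0 at both trivial boundaries;
        # smallest candidate (= lowest observed score) must be returned
        scores = [0.1, 0.2, 0.3, 0.4]
        labels = [0, 1, 0, 1]
        t, j = youden_cutpoint(scores, labels)
        oracle_t, oracle_j = brute_force_youden(scores, labels)
        assert (t, j) == (pytest.approx(oracle_t), pytest.approx(oracle_j))

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            youden_cutpoint([0.9, 0.8], [1, 1])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n = data.draw(st.integers(4, 30))
        scores = data.draw(
            st.lists(
                st.floats(0.5, 1.5, allow_nan=False), min_size=n, max_size=n
            )
        )
        labels = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        if not (any(labels) and not all(labels)):
            labels[0], labels[-1] = True, False
        t, j = youden_cutpoint(scores, labels)
        t_ref, j_ref = brute_force_youden(scores, labels)
        assert j == pytest.approx(j_ref, abs=1e-12)
        assert t == pytest.approx(t_ref, abs=1e-12) or t == t_ref


class TestPredict:
    def test_strictly_below_rule(self):
        model = CutPointModel(cutpoints={Region.M1: 0.9})
        assert predict_region(0.5, model, Region.M1) is True
        assert predict_region(0.9, model, Region.M1) is False  # boundary: not below
        assert predict_region(1.1, model, Region.M1) is False

    def test_unknown_region_rejected(self):
        model = CutPointModel(cutpoints={Region.M1: 0.9})
        with pytest.raises(KeyError):
            predict_region(0.5, model, Region.M2)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.7, 0.8, 0.9, 1.0], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auc([0.9] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_three_of_four_concordant_pairs(self):
        assert auc([0.8, 0.9, 0.85, 0.95], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            auc([0.1, 0.2], [0, 0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.2, 2.0), min_size=6, max_size=40),
        st.sampled_from([np.exp, np.log, lambda x: 3 * x + 1]),
    )
    def test_invariant_under_strictly_monotone_transform(self, scores, f):
        labels = [i % 2 == 0 for i in range(len(scores))]
        base = auc(scores, labels)
        assert auc(f(np.asarray(scores)), labels) == pytest.approx(base, abs=1e-12)


class TestRegionMetrics:
    def test_perfect_split(self):
        m = region_metrics([0.7, 0.8, 1.0, 1.1], [1, 1, 0, 0], threshold=0.9)
        assert (m.auc, m.accuracy, m.sensitivity, m.specificity) == (1, 1, 1, 1)

    def test_threshold_below_all_scores(self):
        m = region_metrics([0.7, 0.8, 1.0], [1, 0, 0], threshold=0.5)
        assert m.sensitivity == 0.0 and m.specificity == 1.0

    def test_single_class_flags_undefined_not_zero(self):
        m = region_metrics([0.7, 0.8], [1, 1], threshold=0.75)
        assert np.isnan(m.auc) and np.isnan(m.specificity)
        assert set(m.undefined) == {"auc", "specificity"}
        assert m.sensitivity == 0.5

    def test_training_threshold_attains_returned_j(self, small_cohort):
        sub = small_cohort[small_cohort["region"] == "Caudate"]
        t, j = youden_cutpoint(sub["rhu"], sub["infarcted"])
        m = region_metrics(sub["rhu"], sub["infarcted"], t)
        assert m.sensitivity + m.specificity - 1 == pytest.approx(j, abs=1e-12)


class TestFit:
    def test_recovers_planted_boundary(self):
        # well-separated classes: optimum must sit between them
        spec = TabularSimSpec(
            n_patients=400, infarcted_mean=0.80, infarcted_sd=0.02,
            normal_mean=1.00, normal_sd=0.02, seed=2,
        )
        model = fit(simulate_tabular(spec))
        for region in Region:
            assert model.cutpoints[region] == pytest.approx(0.90, abs=0.04)
            assert model.youden_j[region] == pytest.approx(1.0, abs=0.05)

    def test_all_negative_region_named_in_error(self, small_cohort):
        table = small_cohort.copy()
        table.loc[table["region"] == "M3", "infarcted"] = False
        with pytest.raises(SingleClassError, match="M3"):
            fit(table)

    def test_json_round_trip(self, small_cohort, tmp_path):
        model = fit(small_cohort)
        model.to_json(tmp_path / "model.json")
        back = CutPointModel.from_json(tmp_path / "model.json")
        assert back.cutpoints == model.cutpoints
        assert back.training_n == model.training_n


class TestCrossValidate:
    def test_perfect_separation_gives_auc_one_in_every_fold(self):
        spec = TabularSimSpec(
            n_patients=120, infarcted_mean=0.70, infarcted_sd=0.01,
            normal_mean=1.10, normal_sd=0.01, seed=4,
        )
        cv = cross_validate(simulate_tabular(spec), k=10, seed=0)
        mean, sd = cv.aggregate["auc"]
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_null_scores_give_chance_auc(self):
        spec = TabularSimSpec(
            n_patients=300, infarcted_mean=0.95, infarcted_sd=0.05,
            normal_mean=0.95, normal_sd=0.05, seed=8,
        )
        cv = cross_validate(simulate_tabular(spec), k=10, seed=1)
        mean, _ = cv.aggregate["auc"]
        assert mean == pytest.approx(0.5, abs=0.05)

    def test_folds_partition_patients(self, small_cohort):
        cv = cross_validate(small_cohort, k=10, seed=3)
        patients = set(small_cohort["patient_id"])
        assert set(cv.fold_assignments) == patients
        sizes = np.bincount(list(cv.fold_assignments.values()), minlength=10)
        assert sizes.sum() == len(patients) and sizes.min() >= len(patients) // 10

    def test_same_seed_reproduces_report(self, small_cohort):
        a = cross_validate(small_cohort, k=5, seed=9)
        b = cross_validate(small_cohort, k=5, seed=9)
        assert a.fold_assignments == b.fold_assignments
        pd.testing.assert_frame_equal(a.per_fold, b.per_fold)

    def test_k_larger_than_n_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="exceeds"):
            cross_validate(small_cohort, k=500, seed=0)

    def test_undefined_cells_are_counted_not_zero_filled(self):
        # tiny cohort with a rare region: some folds have no positives
        spec = TabularSimSpec(n_patients=40, seed=12)
        spec.prevalence[Region.M3] = 0.08
        cv = cross_validate(simulate_tabular(spec), k=10, seed=2)
        assert cv.n_undefined["auc"] >= 1
        for mean, _ in cv.aggregate.values():
            assert np.isfinite(mean)
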