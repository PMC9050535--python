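"""DRS, tailed t tests, AUC, dice and chi-squared utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ieegnorm import (DataError, GOOD_OUTCOME, POOR_OUTCOME, PatientResult,
                      ValidationError, chi2_2x2, dice_overlap, drs,
                      one_sample_t_tailed, patient_drs, roc_auc,
                      run_cohort_analysis, two_sample_t_tailed)

values = st.lists(st.floats(-50, 50).map(lambda v: round(v, 2)),
                  min_size=1, max_size=30)


def brute_force_drs(resected, spared):
    total = 0.0
    for r in resected:
        for s in spared:
            total += 1.0 if s > r else (0.5 if s == r else 0.0)
    return total / (len(resected) * len(spared))


class TestDRS:
    def test_identical_multisets_give_half(self):
        assert drs([1, 2, 3], [1, 2, 3]) == 0.5

    def test_all_spared_more_abnormal(self):
        assert drs([1], [2]) == 1.0

    def test_tied_pair_counts_half(self):
        assert drs([1, 2], [2, 3]) == pytest.approx(0.875)

    def test_empty_group_is_an_error_not_half(self):
        with pytest.raises(DataError):
            drs([], [1.0])
        with pytest.raises(DataError):
            drs([1.0], [])

    @given(a=values, b=values)
    def test_complement_symmetry(self, a, b):
        assert drs(a, b) + drs(b, a) == pytest.approx(1.0, abs=1e-12)

    @given(a=values, b=values)
    def test_matches_brute_force_pairwise_definition(self, a, b):
        assert drs(a, b) == pytest.approx(brute_force_drs(a, b), abs=1e-12)

    @given(a=values, b=values, shift=st.floats(-20, 20))
    def test_rank_statistic_shift_invariance(self, a, b, shift):
        shifted = drs([v + shift for v in a], [v + shift for v in b])
        assert shifted == pytest.approx(drs(a, b), abs=1e-12)

    def test_matches_scipy_mann_whitney(self, rng):
        for _ in range(20):
            a = rng.integers(0, 8, rng.integers(2, 30)).astype(float)
            b = rng.integers(0, 8, rng.integers(2, 30)).astype(float)
            from scipy.stats import mannwhitneyu
            u = mannwhitneyu(b, a, alternative="two-sided").statistic
            assert drs(a, b) == pytest.approx(u / (len(a) * len(b)), abs=1e-12)


class TestPatientDRS:
    def maxz(self, vals, ids):
        return pd.Series(vals, index=pd.Index(ids, name="region_id"))

    def test_patient_level_result(self):
        maxz = self.maxz([3.0, 0.5, 0.4], ["a", "b", "c"])
        res = patient_drs(maxz, pd.Series([True, False, False],
                                          index=maxz.index), "p1")
        assert res.drs == 0.0      # resected region is the most abnormal
        assert (res.n_resected, res.n_spared) == (1, 2)

    def test_patient_without_spared_regions_excluded(self):
        maxz = self.maxz([1.0, 2.0], ["a", "b"])
        with pytest.raises(DataError, match="spared"):
            patient_drs(maxz, pd.Series([True, True], index=maxz.index))


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.2, 0.3, 0.8, 0.9],
                       [GOOD_OUTCOME, GOOD_OUTCOME, POOR_OUTCOME, POOR_OUTCOME]) == 1.0

    def test_identical_score_multisets(self):
        assert roc_auc([0.4, 0.6, 0.4, 0.6],
                       [GOOD_OUTCOME, GOOD_OUTCOME, POOR_OUTCOME, POOR_OUTCOME]) == 0.5

    def test_interleaved_scores(self):
        auc = roc_auc([0.4, 0.6, 0.5, 0.7],
                      [GOOD_OUTCOME, GOOD_OUTCOME, POOR_OUTCOME, POOR_OUTCOME])
        assert auc == pytest.approx(0.75)

    def test_single_class_errors(self):
        with pytest.raises(DataError):
            roc_auc([0.1, 0.2], [GOOD_OUTCOME, GOOD_OUTCOME])

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.uniform(0, 1, 40)
        labels = np.where(rng.random(40) < 0.5, POOR_OUTCOME, GOOD_OUTCOME)
        if len(set(labels)) < 2:
            labels[:2] = [GOOD_OUTCOME, POOR_OUTCOME]
        expected = roc_auc_score((labels == POOR_OUTCOME).astype(int), scores)
        assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(0.01, 0.99), min_size=4, max_size=20))
    def test_invariant_under_monotone_transform(self, scores):
        labels = [GOOD_OUTCOME, POOR_OUTCOME] * (len(scores) // 2)
        scores = scores[:len(labels)]
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(5 * np.asarray(scores)), labels)
        assert a == pytest.approx(b, abs=1e-12)


class TestTailedT:
    def test_one_sample_right_tail_hand_computed(self):
        t, p = one_sample_t_tailed([0.6, 0.7, 0.8], 0.5, tail="right")
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert p < 0.05

    def test_one_sample_tails_are_complementary(self):
        vals = [0.42, 0.55, 0.61, 0.47]
        _, p_left = one_sample_t_tailed(vals, 0.5, "left")
        flipped = [0.5 - (v - 0.5) for v in vals]
        _, p_right = one_sample_t_tailed(flipped, 0.5, "right")
        assert p_left == pytest.approx(p_right, rel=1e-10)

    def test_zero_variance_errors(self):
        with pytest.raises(DataError, match="variance"):
            one_sample_t_tailed([0.5, 0.5, 0.5])

    def test_two_sample_pooled_hand_computed(self):
        t, _ = two_sample_t_tailed([0.1, 0.2], [0.8, 0.9], "left")
        assert t == pytest.approx(-9.899, abs=1e-3)

    def test_two_sample_identical_groups(self):
        t, p = two_sample_t_tailed([0.4, 0.5, 0.6], [0.4, 0.5, 0.6], "left")
        assert t == 0.0
        assert p == pytest.approx(0.5)

    def test_two_sample_antisymmetric_in_groups(self):
        a, b = [0.1, 0.3, 0.2], [0.5, 0.4, 0.6]
        t_ab, _ = two_sample_t_tailed(a, b, "left")
        t_ba, _ = two_sample_t_tailed(b, a, "left")
        assert t_ab == pytest.approx(-t_ba)

    def test_underpowered_group_errors(self):
        with pytest.raises(DataError):
            two_sample_t_tailed([0.1], [0.4, 0.5])


class TestDiceChi2:
    def test_dice_identical_sets(self):
        assert dice_overlap({"r1", "r2"}, {"r1", "r2"}) == 1.0

    def test_dice_disjoint_sets(self):
        assert dice_overlap({"r1"}, {"r2"}) == 0.0

    def test_dice_half_overlap(self):
        assert dice_overlap({"r1", "r2"}, {"r2", "r3"}) == 0.5

    def test_dice_both_empty_errors(self):
        with pytest.raises(DataError):
            dice_overlap(set(), set())

    def test_chi2_lobe_by_outcome_table(self):
        chi2, p = chi2_2x2([[21, 15], [12, 14]])
        assert chi2 == pytest.approx(0.8995, abs=1e-3)
        assert p == pytest.approx(0.34, abs=0.01)

    def test_chi2_sex_by_outcome_table(self):
        chi2, p = chi2_2x2([[15, 17], [18, 12]])
        assert chi2 == pytest.approx(1.07, abs=0.01)

    def test_chi2_independence_is_zero(self):
        chi2, p = chi2_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0

    @given(st.tuples(*[st.integers(1, 40)] * 4))
    def test_chi2_transpose_invariant(self, counts):
        a, b, c, d = counts
        t1, _ = chi2_2x2([[a, b], [c, d]])
        t2, _ = chi2_2x2([[a, c], [b, d]])
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_chi2_zero_margin_errors(self):
        with pytest.raises(DataError, match="margin"):
            chi2_2x2([[0, 0], [5, 7]])


class TestCohortAnalysis:
    def make_patients(self, good_scores, poor_scores):
        out = [PatientResult(f"g{i}", s, 3, 5, GOOD_OUTCOME)
               for i, s in enumerate(good_scores)]
        out += [PatientResult(f"p{i}", s, 3, 5, POOR_OUTCOME)
                for i, s in enumerate(poor_scores)]
        return out

    def test_separated_groups_detected(self, rng):
        good = np.clip(rng.normal(0.3, 0.1, 30), 0, 1)
        poor = np.clip(rng.normal(0.7, 0.1, 30), 0, 1)
        res = run_cohort_analysis(self.make_patients(good, poor))
        assert res.auc > 0.95
        assert res.good_vs_poor[1] < 1e-6
        assert res.good_below_half[1] < 0.01
        assert res.poor_above_half[1] < 0.01

    def test_null_cohort_near_chance(self, rng):
        scores = 0.5 + 0.01 * rng.standard_normal(60)
        res = run_cohort_analysis(self.make_patients(scores[:30], scores[30:]))
        assert res.auc == pytest.approx(0.5, abs=0.15)

    def test_single_group_cohort_errors(self):
        with pytest.raises(DataError):
            run_cohort_analysis(self.make_patients([0.4, 0.5], []))

    def test_unknown_outcome_label_rejected(self):
        bad = [PatientResult("x", 0.4, 1, 1, "ILAE9")]
        with pytest.raises(ValidationError, match="outcome"):
            run_cohort_analysis(bad)
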