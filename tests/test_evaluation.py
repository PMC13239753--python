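"""Residual-correlation profiling, success criteria and reference intervals."""

import numpy as np
import pytest

import aortanorm as an
from aortanorm.core import AorticParam, predict_yp
from aortanorm.equations import CHINESE
from aortanorm.evaluation import (
    CorrelationEntry,
    assess_efficacy,
    classify_residual,
    classify_subject,
    efficacy_table,
    format_p,
    pearson_with_p,
    reference_interval,
    residual_profile,
    success_rate,
)


class TestPearson:
    def test_hand_computed_example(self):
        entry = pearson_with_p([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert entry.r == pytest.approx(0.8, abs=1e-12)
        assert entry.n == 5

    def test_perfect_linearity(self):
        entry = pearson_with_p([1, 2, 7, 9], [3, 5, 15, 19])
        assert entry.r == pytest.approx(1.0)
        assert entry.p < 1e-6

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4])

    def test_mismatched_or_short_series_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            pearson_with_p([1, 2], [3, 4])


class TestClassification:
    @pytest.mark.parametrize(
        "r,p,expected",
        [
            (-0.451, 0.0005, "overcorrected"),
            (-0.133, 0.028, "overcorrected"),
            (0.31, 0.001, "undercorrected"),
            (0.05, 0.40, "acceptable"),
            (-0.5, 0.20, "acceptable"),
        ],
    )
    def test_residual_annotation(self, r, p, expected):
        assert classify_residual(CorrelationEntry("age", r, p, 273)) == expected

    def test_small_significant_correlation_does_not_fail_criterion_1(self, small_cohort):
        # An entry like (r = -0.133, p = 0.028) is annotated overcorrected yet
        # passes the success gate, which needs BOTH |r| > 0.20 and p < 0.05.
        ages = np.array([s.age for s in small_cohort])
        yu = np.array([s.dims[AorticParam.AO_A] for s in small_cohort])
        yp = np.array([predict_yp(CHINESE["ao_a"], s) for s in small_cohort])
        # well-corrected ratios with a weak negative age trend superimposed
        corrected = yu / yp - 0.0013 * (ages - ages.mean())
        report = assess_efficacy(corrected, yu, small_cohort, "ao_a")
        age_entry = next(e for e in report.entries if e.variable == "age")
        assert age_entry.r < 0 and abs(age_entry.r) <= 0.20
        assert report.criterion1_pass
        assert report.success


class TestResidualProfile:
    def test_null_values_show_no_biological_correlations(self, small_cohort, rng):
        values = rng.normal(1.0, 0.11, len(small_cohort))
        entries = residual_profile(values, small_cohort)
        assert {e.variable for e in entries} == {"age", "height", "weight", "bsa", "bmi"}
        assert not any(abs(e.r) > 0.20 and e.p < 0.05 for e in entries)

    def test_values_equal_to_age_correlate_perfectly(self, small_cohort):
        values = [s.age for s in small_cohort]
        age_entry = next(
            e for e in residual_profile(values, small_cohort) if e.variable == "age"
        )
        assert age_entry.r == pytest.approx(1.0)

    def test_bsa_indexation_overcorrects_simulated_cohort(self, chinese_cohort):
        # Dividing by BSA flips the body-size correlations negative.
        indexed = [an.index_bsa(s.dims[AorticParam.AO_A], s.bsa) for s in chinese_cohort]
        bsa_entry = next(
            e for e in residual_profile(indexed, chinese_cohort) if e.variable == "bsa"
        )
        assert bsa_entry.r < 0 and bsa_entry.p < 0.05

    def test_length_mismatch_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            residual_profile([1.0, 2.0], small_cohort)


class TestEfficacy:
    def test_model_correction_succeeds_on_its_own_cohort(self, chinese_cohort):
        yu = np.array([s.dims[AorticParam.AO_S] for s in chinese_cohort])
        yp = np.array([predict_yp(CHINESE["ao_s"], s) for s in chinese_cohort])
        report = assess_efficacy(yu / yp, yu, chinese_cohort, "ao_s", "chinese", "omam")
        assert report.success
        assert report.criterion1_pass and report.criterion2_pass

    def test_bsa_indexation_fails_on_same_cohort(self, chinese_cohort):
        yu = np.array([s.dims[AorticParam.AO_S] for s in chinese_cohort])
        bsa = np.array([s.bsa for s in chinese_cohort])
        report = assess_efficacy(yu / bsa, yu, chinese_cohort, "ao_s", "chinese", "bsa")
        assert not report.success
        assert not report.criterion1_pass

    def test_independent_corrected_series_fails_criterion_2(self, small_cohort, rng):
        yu = np.array([s.dims[AorticParam.AO_A] for s in small_cohort])
        corrected = rng.normal(1.0, 0.1, len(small_cohort))
        report = assess_efficacy(corrected, yu, small_cohort, "ao_a")
        assert not report.criterion2_pass
        assert not report.success

    def test_success_rate_arithmetic_and_bounds(self, small_cohort, rng):
        yu = np.array([s.dims[AorticParam.AO_A] for s in small_cohort])
        good = assess_efficacy(
            yu / np.array([predict_yp(CHINESE["ao_a"], s) for s in small_cohort]),
            yu, small_cohort, "ao_a",
        )
        bad = assess_efficacy(rng.normal(1, 0.1, len(yu)), yu, small_cohort, "ao_a")
        assert success_rate([good, bad]) == pytest.approx(50.0)
        assert success_rate([bad, good]) == pytest.approx(50.0)  # permutation invariant
        assert 0.0 <= success_rate([bad]) <= 100.0
        with pytest.raises(ValueError):
            success_rate([])

    def test_report_serialization_and_table(self, small_cohort):
        yu = np.array([s.dims[AorticParam.AO_A] for s in small_cohort])
        yp = np.array([predict_yp(CHINESE["ao_a"], s) for s in small_cohort])
        report = assess_efficacy(yu / yp, yu, small_cohort, "ao_a", "chinese", "omam")
        d = report.to_dict()
        assert d["success"] == (d["criterion1_pass"] and d["criterion2_pass"])
        table = efficacy_table([report])
        assert list(table.columns)[:2] == ["indexation", "uncorrected"]
        assert len(table) == 1


class TestGroupComparisons:
    def test_identical_gender_groups_give_p_one(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        genders = [0, 0, 0, 1, 1, 1]
        mean_m, mean_w, p = an.gender_difference_test(values, genders)
        assert mean_m == mean_w
        assert p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        mean_m, mean_w, p = an.gender_difference_test(
            [1, 2, 3, 2, 3, 4], [0, 0, 0, 1, 1, 1]
        )
        assert (mean_m, mean_w) == (2.0, 3.0)
        assert p == pytest.approx(0.2878641, abs=1e-6)

    def test_single_gender_rejected(self):
        with pytest.raises(ValueError):
            an.gender_difference_test([1, 2, 3], [0, 0, 0])

    def test_corrected_values_show_no_gender_difference(self, chinese_cohort):
        genders = [s.gender for s in chinese_cohort]
        yc = [
            s.dims[AorticParam.AO_A] / predict_yp(CHINESE["ao_a"], s)
            for s in chinese_cohort
        ]
        *_, p = an.gender_difference_test(yc, genders)
        assert p > 0.05

    def test_anova_identical_groups(self):
        f, p = an.age_group_anova([2.0] * 9, ["a", "b", "c"] * 3)
        assert (f, p) == (0.0, 1.0)

    def test_anova_hand_computed_f(self):
        # groups (1,2), (3,4), (5,6): SSB = 16 (df 2), SSW = 1.5 (df 3),
        # so F = (16/2) / (1.5/3) = 8 / 0.5 = 16.
        f, p = an.age_group_anova(
            [1, 2, 3, 4, 5, 6], ["g1", "g1", "g2", "g2", "g3", "g3"]
        )
        assert f == pytest.approx(16.0, abs=1e-9)

    def test_anova_needs_two_groups(self):
        with pytest.raises(ValueError):
            an.age_group_anova([1, 2, 3], ["a", "a", "a"])

    def test_uncorrected_values_vary_across_age_groups(self, chinese_cohort):
        # the ascending aorta grows with age (positive age exponent in truth)
        groups = [an.assign_age_group(s.age) for s in chinese_cohort]
        values = [s.dims[AorticParam.AO_ASC] for s in chinese_cohort]
        _, p = an.age_group_anova(values, groups)
        assert p < 0.05


class TestReferenceInterval:
    def test_constant_series_is_degenerate_and_flagged(self):
        iv = reference_interval([1.0] * 50, method="percentile")
        assert iv.degenerate
        assert iv.lower == iv.upper == 1.0

    def test_percentile_interval_matches_lognormal_quantiles(self, rng):
        values = np.exp(rng.normal(0.0, 0.11, 100_000))
        iv = reference_interval(values, method="percentile")
        assert iv.lower == pytest.approx(0.806, abs=0.01)
        assert iv.upper == pytest.approx(1.241, abs=0.01)

    def test_normal_theory_interval(self, rng):
        values = rng.normal(1.002, 0.112, 5000)
        iv = reference_interval(values, method="normal_theory")
        assert iv.lower == pytest.approx(iv.mean - 1.96 * iv.sd)
        assert iv.upper == pytest.approx(iv.mean + 1.96 * iv.sd)
        assert iv.lower == pytest.approx(0.782, abs=0.02)

    def test_sample_size_gate(self):
        with pytest.raises(ValueError):
            reference_interval(np.ones(30) + np.arange(30), method="percentile")
        with pytest.raises(ValueError):
            reference_interval([1.0], method="normal_theory")
        with pytest.raises(ValueError):
            reference_interval(np.ones(50), method="bootstrap")


class TestSubjectClassification:
    @pytest.mark.parametrize(
        "yc,expected",
        [(1.00, "normal"), (1.30, "increased"), (0.70, "decreased"),
         (0.794, "normal"), (1.246, "normal")],
    )
    def test_against_published_interval(self, yc, expected):
        interval = CHINESE.interval_for("ao_a")  # (0.794, 1.246)
        assert classify_subject(yc, interval) == expected


def test_p_value_formatting():
    assert format_p(0.0004) == "<0.001"
    assert format_p(0.028) == "0.028"
    assert format_p(0.5) == "0.500"
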