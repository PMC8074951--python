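import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wearcohort.compare import (
    CompareConfig,
    assess_normality,
    build_pairs,
    paired_t,
    run_comparison,
    standard_comparisons,
    wilcoxon_signed_rank,
)
from wearcohort.pipeline import analyze_dataset


def summary_rows(variable, label, year, means):
    return pd.DataFrame(
        {
            "participant_id": list(means),
            "period_label": label,
            "year": year,
            "variable": variable,
            "mean_per_day": list(means.values()),
            "n_valid_days": 10,
        }
    )


def two_period_summaries(a_means, b_means, variable="steps", key_a=("March", 2019), key_b=("March 13-31", 2020)):
    return pd.concat(
        [
            summary_rows(variable, key_a[0], key_a[1], a_means),
            summary_rows(variable, key_b[0], key_b[1], b_means),
        ],
        ignore_index=True,
    )


class TestBuildPairs:
    def test_intersection_of_participants(self):
        s = two_period_summaries({"p1": 1.0, "p2": 2.0, "p3": 3.0}, {"p2": 5.0, "p3": 6.0, "p4": 7.0})
        pair = build_pairs(s, "steps", ("March", 2019), ("March 13-31", 2020))
        assert pair.participant_ids == ("p2", "p3")
        assert pair.n == 2
        np.testing.assert_allclose(pair.diffs, [3.0, 3.0])

    def test_identical_periods_give_zero_diffs(self):
        means = {"p1": 4.0, "p2": 8.0}
        pair = build_pairs(two_period_summaries(means, means), "steps", ("March", 2019), ("March 13-31", 2020))
        assert (pair.diffs == 0).all()

    def test_disjoint_participants_rejected(self):
        s = two_period_summaries({"p1": 1.0, "p2": 2.0}, {"p3": 3.0, "p4": 4.0})
        with pytest.raises(ValueError, match="insufficient pairs"):
            build_pairs(s, "steps", ("March", 2019), ("March 13-31", 2020))

    def test_n_pairs_bounded_by_each_period(self):
        s = two_period_summaries({"p1": 1.0, "p2": 2.0, "p3": 3.0}, {"p2": 5.0, "p3": 6.0})
        pair = build_pairs(s, "steps", ("March", 2019), ("March 13-31", 2020))
        assert pair.n <= 2


class TestPairedT:
    def test_textbook_example(self):
        # diffs [1,2,3]: mean 2, sd 1, t = 2/(1/sqrt(3)) = 3.4641, df = 2
        res = paired_t(np.array([1.0, 2.0, 3.0]))
        assert res.mean_diff == pytest.approx(2.0)
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)
        assert res.p_two_sided == pytest.approx(0.0742, abs=1e-4)
        assert res.ci_low < res.mean_diff < res.ci_high

    def test_symmetric_pair_is_exactly_null(self):
        res = paired_t(np.array([-1.0, 1.0]))
        assert res.mean_diff == 0 and res.statistic == 0 and res.p_two_sided == 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        diffs = rng.normal(1, 2, 20)
        a, b = paired_t(diffs), paired_t(rng.permutation(diffs))
        assert a.p_two_sided == pytest.approx(b.p_two_sided, rel=1e-12)
        assert a.mean_diff == pytest.approx(b.mean_diff, rel=1e-12)

    def test_sign_flip_antisymmetry(self):
        diffs = np.array([0.3, 1.2, -0.5, 2.0, 0.9])
        a, b = paired_t(diffs), paired_t(-diffs)
        assert a.p_two_sided == pytest.approx(b.p_two_sided, rel=1e-12)
        assert a.mean_diff == pytest.approx(-b.mean_diff, rel=1e-12)
        assert a.ci_low == pytest.approx(-b.ci_high, rel=1e-12)

    def test_zero_variance_is_degenerate(self):
        res = paired_t(np.array([2.0, 2.0, 2.0]))
        assert res.degenerate and np.isnan(res.p_two_sided)
        assert res.mean_diff == 2.0


class TestWilcoxon:
    def test_all_positive_three(self):
        # all-positive signs among the 2^3 equally likely sign patterns
        res = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]))
        assert res.p_two_sided == pytest.approx(0.25)
        assert res.median_diff == 2.0
        assert res.n_effective == 3

    def test_tied_magnitudes_perfect_symmetry(self):
        assert wilcoxon_signed_rank(np.array([-1.0, 1.0])).p_two_sided == pytest.approx(1.0)

    def test_zeros_dropped_by_default(self):
        res = wilcoxon_signed_rank(np.array([0.0, 0.0, 5.0]))
        assert res.n_effective == 1
        assert res.p_two_sided == pytest.approx(1.0)
        # location/IQR still computed on the raw diffs, zeros included
        assert res.median_diff == 0.0

    def test_estimate_is_raw_median_and_iqr(self):
        diffs = np.array([-6.0, -2.0, 0.0, 4.0, 10.0])
        res = wilcoxon_signed_rank(diffs)
        assert res.median_diff == 0.0
        assert (res.iqr_low, res.iqr_high) == (np.percentile(diffs, 25), np.percentile(diffs, 75))

    def test_all_zero_diffs_degenerate(self):
        res = wilcoxon_signed_rank(np.zeros(4))
        assert res.degenerate and np.isnan(res.p_two_sided)

    def test_pratt_zero_handling_available(self):
        res = wilcoxon_signed_rank(np.array([0.0, 1.0, 2.0, -3.0]), zero_method="pratt")
        expected = stats.wilcoxon([0.0, 1.0, 2.0, -3.0], zero_method="pratt", method="approx").pvalue
        assert res.p_two_sided == pytest.approx(expected)

    def test_exact_matches_enumeration_small_n(self):
        # exhaustive oracle: all sign assignments of distinct magnitudes
        magnitudes = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ranks = stats.rankdata(magnitudes)
        null = np.array(
            [ranks[np.array(signs, bool)].sum() for signs in itertools.product([0, 1], repeat=5)]
        )
        for signs in itertools.product([1, -1], repeat=5):
            diffs = magnitudes * np.array(signs)
            w_plus = ranks[diffs > 0].sum()
            expected = min(1.0, 2 * min((null <= w_plus).mean(), (null >= w_plus).mean()))
            assert wilcoxon_signed_rank(diffs).p_two_sided == pytest.approx(expected)

    def test_large_n_normal_approximation_with_ties(self):
        rng = np.random.default_rng(5)
        diffs = np.round(rng.normal(0.5, 2, 60))  # heavy ties, n > 25
        res = wilcoxon_signed_rank(diffs)
        kept = diffs[diffs != 0]
        expected = stats.wilcoxon(kept, method="approx").pvalue
        assert res.p_two_sided == pytest.approx(expected)


class TestNormalityAssessment:
    def test_normal_differences_usually_pass(self):
        rng = np.random.default_rng(11)
        accepted = sum(assess_normality(rng.normal(size=100)) for _ in range(300)) / 300
        assert 0.90 <= accepted <= 0.99

    def test_skewed_differences_usually_fail(self):
        rng = np.random.default_rng(12)
        rejected = sum(not assess_normality(rng.exponential(size=100) - 1) for _ in range(300)) / 300
        assert rejected >= 0.98

    def test_constant_differences_degenerate_false(self):
        assert assess_normality(np.full(10, 3.0)) is False

    def test_too_few_differences_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            assess_normality(np.array([1.0, 2.0]))


class TestRunComparison:
    def test_shipped_override_sends_mvpa_to_wilcoxon(self):
        rng = np.random.default_rng(2)
        means_a = {f"p{i}": v for i, v in enumerate(rng.normal(30, 5, 20))}
        means_b = {k: v + rng.normal(2, 1) for k, v in means_a.items()}
        s = two_period_summaries(means_a, means_b, variable="mvpa")
        res = run_comparison(s, "mvpa", ("March", 2019), ("March 13-31", 2020))
        assert res.test == "wilcoxon_signed_rank"

    def test_auto_mode_picks_t_for_normal_diffs(self):
        rng = np.random.default_rng(4)
        means_a = {f"p{i}": v for i, v in enumerate(rng.normal(8000, 500, 40))}
        means_b = {k: v + rng.normal(100, 50) for k, v in means_a.items()}
        s = two_period_summaries(means_a, means_b)
        config = CompareConfig(test_overrides={})
        res = run_comparison(s, "steps", ("March", 2019), ("March 13-31", 2020), config)
        assert res.test == "paired_t"

    def test_same_period_twice_is_degenerate(self):
        means = {"p1": 4.0, "p2": 8.0, "p3": 1.0}
        s = two_period_summaries(means, means)
        res = run_comparison(s, "steps", ("March", 2019), ("March 13-31", 2020))
        assert res.degenerate and not res.significant

    def test_significance_flag_matches_alpha(self):
        means_a = {f"p{i}": float(i) for i in range(10)}
        means_b = {k: v + 5.0 + 0.01 * i for i, (k, v) in enumerate(means_a.items())}
        s = two_period_summaries(means_a, means_b)
        res = run_comparison(s, "steps", ("March", 2019), ("March 13-31", 2020))
        assert res.significant == (res.p_two_sided < 0.05)


class TestFullReport:
    def test_complete_cohort_yields_13x3_cells(self, small_lockdown_cohort):
        outputs = analyze_dataset(small_lockdown_cohort)
        report = outputs.report
        assert len(report) == 39
        assert report["comparison_label"].nunique() == 13
        assert set(report["variable"]) == {"steps", "aee", "mvpa"}
        labels = [label for label, _, _ in standard_comparisons()]
        assert list(report["comparison_label"].drop_duplicates()) == labels

    def test_lockdown_rows_show_negative_step_estimate(self, small_lockdown_cohort):
        report = analyze_dataset(small_lockdown_cohort).report
        row = report[(report["comparison_label"] == "March 13-31") & (report["variable"] == "steps")]
        assert row["estimate"].iloc[0] < 0

    def test_missing_month_omitted_with_warning(self, small_lockdown_cohort, caplog):
        frame = small_lockdown_cohort.frame
        trimmed = frame[frame["date"].dt.month != 12]
        from wearcohort.ingest import CanonicalDataset

        with caplog.at_level("WARNING"):
            report = analyze_dataset(CanonicalDataset(trimmed)).report
        assert "December" not in set(report["comparison_label"])
        assert report["comparison_label"].nunique() == 12
        assert any("December" in m for m in caplog.messages)

    def test_single_year_gives_empty_report(self, small_lockdown_cohort, caplog):
        frame = small_lockdown_cohort.frame
        only_2019 = frame[frame["date"].dt.year == 2019]
        from wearcohort.ingest import CanonicalDataset

        with caplog.at_level("WARNING"):
            report = analyze_dataset(CanonicalDataset(only_2019)).report
        assert report.empty
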