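"""Responder grouping, Ki-67 change and the nonparametric test battery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ivimtools.roi import RoiSummary
from ivimtools.stats import (
    CohortTable,
    PatientRecord,
    assign_response_group,
    ki67_percent_change,
    median_iqr,
    run_cohort_analysis,
    shapiro_wilk,
    spearman_correlation,
    wilcoxon_rank_sum,
)


class TestGroupingAndKi67:
    @pytest.mark.parametrize("grade,expected", [
        (1, "poor"), (2, "poor"), (3, "poor"), (4, "good"), (5, "good"),
    ])
    def test_miller_payne_grouping(self, grade, expected):
        assert assign_response_group(grade) == expected

    @pytest.mark.parametrize("bad", [0, 6, -1])
    def test_out_of_range_grade(self, bad):
        with pytest.raises(ValueError):
            assign_response_group(bad)

    def test_ki67_change_worked_examples(self):
        assert ki67_percent_change(17.5, 0.8) == pytest.approx(-95.43, abs=5e-3)
        assert ki67_percent_change(23.7, 12.4) == pytest.approx(-47.68, abs=5e-3)
        assert ki67_percent_change(20, 20) == 0.0

    def test_zero_biopsy_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ki67_percent_change(0.0, 5.0)


class TestShapiroWilk:
    def test_large_normal_sample(self):
        x = np.random.default_rng(0).normal(size=500)
        r = shapiro_wilk(x)
        assert r.statistic > 0.99
        assert r.p_value > 0.001

    def test_power_against_exponential(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            shapiro_wilk(rng.exponential(size=50)).p_value < 0.05 for _ in range(40))
        assert rejections >= 36  # overwhelming majority of seeds

    def test_domain_contract(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk([3.0] * 10)


def _wilcoxon_enumeration_p(a, b):
    """Independent oracle: exact two-sided p by enumerating rank splits."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na = len(a)
    w_obs = ranks[:na].sum()
    mean_w = na * (len(pooled) + 1) / 2.0
    dev_obs = abs(w_obs - mean_w)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), na):
        w = ranks[list(comb)].sum()
        count += abs(w - mean_w) >= dev_obs - 1e-9
        total += 1
    return count / total


class TestWilcoxonRankSum:
    def test_textbook_extreme_case(self):
        r = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert r.p_value == pytest.approx(0.10, abs=1e-12)
        assert r.method == "wilcoxon_rank_sum_exact"

    def test_identical_multisets_p_one(self):
        r = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("na,nb", [(2, 2), (3, 4), (5, 3), (6, 6), (4, 6)])
    def test_matches_enumeration_oracle(self, na, nb):
        rng = np.random.default_rng(100 * na + nb)
        for _ in range(5):
            a, b = rng.normal(size=na), rng.normal(size=nb) + rng.normal()
            ours = wilcoxon_rank_sum(a, b).p_value
            assert ours == pytest.approx(_wilcoxon_enumeration_p(a, b), abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=5), rng.normal(size=7)
        p1 = wilcoxon_rank_sum(a, b).p_value
        p2 = wilcoxon_rank_sum(np.exp(a), np.exp(b)).p_value
        assert p1 == p2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


def _spearman_permutation_p(x, y):
    """Independent oracle: exact p from all n! permutations of one margin."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)

    def rho(u, v):
        u, v = u - u.mean(), v - v.mean()
        return (u @ v) / math.sqrt((u @ u) * (v @ v))

    obs = abs(rho(rx, ry))
    count = total = 0
    for perm in itertools.permutations(ry):
        count += abs(rho(rx, np.array(perm))) >= obs - 1e-9
        total += 1
    return count / total


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_correlation(x, [2, 4, 9, 16, 30]).estimate == 1.0
        assert spearman_correlation(x, [-1, -2, -3, -4, -9]).estimate == -1.0

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_exact_p_matches_full_permutation(self, n):
        rng = np.random.default_rng(n)
        for _ in range(3):
            x, y = rng.normal(size=n), rng.normal(size=n)
            ours = spearman_correlation(x, y)
            assert ours.method == "spearman_exact"
            assert ours.p_value == pytest.approx(_spearman_permutation_p(x, y), abs=1e-12)

    def test_rho_with_ties_matches_scipy(self):
        x = [1, 2, 2, 3, 5, 5, 6, 8, 9, 10, 11, 3]
        y = [2, 1, 4, 4, 6, 7, 7, 9, 8, 12, 11, 5]
        ours = spearman_correlation(x, y)
        ref = sps.spearmanr(x, y)
        assert ours.estimate == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=8), rng.normal(size=8)
        a = spearman_correlation(x, y)
        b = spearman_correlation(np.exp(x), y**3)
        assert a.estimate == pytest.approx(b.estimate)
        assert a.p_value == pytest.approx(b.p_value)

    def test_domain_contracts(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])


class TestMedianIqr:
    def test_linear_interpolation_convention(self):
        m, q1, q3 = median_iqr([1, 2, 3, 4])
        assert (m, q1, q3) == (2.5, 1.75, 3.25)  # R type 7

    def test_duplication_counterexample(self):
        # duplicating data shifts interpolated quartiles: not idempotent
        base = median_iqr([1, 2, 3])
        doubled = median_iqr([1, 1, 2, 2, 3, 3])
        assert base[0] == doubled[0]
        assert base[1] != doubled[1]  # 1.5 vs 1.25 under linear interpolation


def _make_cohort(good_changes, poor_changes, ki67_changes=None):
    records = []
    all_changes = list(good_changes) + list(poor_changes)
    n = len(all_changes)
    ki67_changes = ki67_changes or [-50.0] * n
    for i, chg in enumerate(all_changes):
        grade = 5 if i < len(good_changes) else 2
        base = RoiSummary(10.0, 1.0, 6.0, 50, 50)
        cyc = RoiSummary(10.0 * (1 + chg / 100), 1.1, 5.5, 50, 50)
        biopsy = 20.0
        records.append(PatientRecord(
            patient_id=f"P{i}", miller_payne_grade=grade,
            ki67_biopsy=biopsy,
            ki67_excision=biopsy * (1 + ki67_changes[i] / 100),
            baseline=base, cycle1=cyc))
    return CohortTable(records)


class TestCohortAnalysis:
    def test_fully_separated_groups_highly_significant(self):
        rng = np.random.default_rng(2)
        good = sorted(rng.uniform(-30, -10, 7))
        poor = sorted(rng.uniform(5, 30, 9))
        rep = run_cohort_analysis(_make_cohort(good, poor))
        assert rep.tests["wilcoxon_change_f"].p_value < 0.001

    def test_identical_groups_no_flags(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        rep = run_cohort_analysis(_make_cohort(vals, vals))
        assert rep.tests["wilcoxon_change_f"].p_value == pytest.approx(1.0)
        assert rep.tests["wilcoxon_baseline_f"].p_value == pytest.approx(1.0)
        assert not rep.tests["wilcoxon_change_f"].significant

    def test_small_group_comparison_skipped(self):
        rep = run_cohort_analysis(_make_cohort([-10.0], [5.0, 6.0, 7.0]))
        assert any("wilcoxon_change_f" in s for s in rep.skipped)

    def test_missing_cycle1_kept_in_baseline_only(self):
        table = _make_cohort([-10, -12, -15], [5, 8, 9, 11])
        table.records[0].cycle1 = None
        df = table.to_frame()
        assert df["pct_change_f"].notna().sum() == 6
        rep = run_cohort_analysis(table)
        assert rep.tests["wilcoxon_baseline_f"].n == (3, 4)
        assert rep.tests["wilcoxon_change_f"].n == (2, 4)

    def test_duplicate_patient_ids_rejected(self):
        df = _make_cohort([-10, -11], [5, 6]).to_frame()
        df.loc[1, "patient_id"] = df.loc[0, "patient_id"]
        with pytest.raises(ValueError):
            run_cohort_analysis(df)

    def test_report_table_shape(self):
        rep = run_cohort_analysis(_make_cohort([-10, -12, -15], [5, 8, 9, 11]))
        assert list(rep.table["marker"]) == ["f", "D", "D*"]
        for col in ("baseline_all", "change_good", "p_change", "rho_ki67_change"):
            assert col in rep.table.columns
        text = rep.to_text()
        assert "hypothesis tests" in text
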