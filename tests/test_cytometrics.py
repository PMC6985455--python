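"""Cell-level statistics: chi-squared, proportions, rank tests, MT rates."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cinsynergy.cytometrics import (
    chi_squared_test,
    mitotic_timing_summary,
    mt_rate_comparison,
    proportion_summary,
    rank_sum_test,
)
from cinsynergy.errors import AnalysisError, DegenerateTableError


class TestChiSquared:
    def test_identical_proportions_give_zero_statistic(self):
        tab = pd.DataFrame([[40, 60], [80, 120]], columns=["normal", "abnormal"])
        res = chi_squared_test(tab)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_direct_formula_on_2x2(self):
        # oracle: hand-computed sum of (O - E)^2 / E
        counts = np.array([[46.0, 54.0], [1.0, 99.0]])
        row, col, n = counts.sum(1), counts.sum(0), counts.sum()
        expected = np.outer(row, col) / n
        direct = ((counts - expected) ** 2 / expected).sum()
        res = chi_squared_test(pd.DataFrame(counts), correction=False)
        assert res.statistic == pytest.approx(direct, rel=1e-12)
        assert res.dof == 1
        assert res.p == pytest.approx(stats.chi2.sf(direct, 1), rel=1e-12)

    def test_zero_row_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi_squared_test(pd.DataFrame([[0, 0], [10, 20]]))

    def test_small_expected_counts_warn(self):
        with pytest.warns(UserWarning, match="expected count"):
            chi_squared_test(pd.DataFrame([[2, 30], [3, 40]]))

    def test_scaling_counts_shrinks_p_at_fixed_proportions(self):
        tab = pd.DataFrame([[45, 55], [55, 45]])
        p1 = chi_squared_test(tab).p
        p10 = chi_squared_test(tab * 10).p
        assert p10 < p1


class TestProportionSummary:
    def test_aneuploid_fraction_worked_example(self):
        # 76 aneuploid of 169 sequenced knockdown cells -> 45%
        res = proportion_summary(76, 169)
        assert res.percent_rounded == 45
        assert res.ci_low_pct < 45 < res.ci_high_pct

    def test_control_fraction(self):
        assert proportion_summary(2, 114).percent == pytest.approx(1.7543859, rel=1e-6)

    def test_zero_count(self):
        assert proportion_summary(0, 50).percent == 0.0

    def test_complement_sums_to_hundred(self):
        a = proportion_summary(76, 169).percent
        b = proportion_summary(169 - 76, 169).percent
        assert a + b == pytest.approx(100.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_summary(1, 0)
        with pytest.raises(ValueError):
            proportion_summary(5, 4)


class TestRankSum:
    def test_identical_samples_vacuous(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == 1.0
        assert res.tied

    def test_separated_3v3_matches_exhaustive_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        res = rank_sum_test(a, b)
        assert res.method == "exact"
        # oracle: enumerate all C(6,3) = 20 rank assignments; under the
        # symmetric null the two-sided p is 2 * P(rank sum <= observed)
        ranks = np.arange(1, 7)
        observed = sum(stats.rankdata(a + b)[:3])
        assignments = list(itertools.combinations(ranks, 3))
        assert len(assignments) == 20
        lower = sum(1 for c in assignments if sum(c) <= observed)
        assert res.p == pytest.approx(2 * lower / 20)
        assert res.p == pytest.approx(0.1)

    def test_exact_and_asymptotic_agree_at_crossover(self, rng):
        # median agreement within 0.01 at combined n = 12
        diffs = []
        for _ in range(60):
            a = rng.normal(0.0, 1.0, 6)
            b = rng.normal(0.6, 1.0, 6)
            pe = stats.mannwhitneyu(a, b, method="exact").pvalue
            pa = stats.mannwhitneyu(a, b, method="asymptotic").pvalue
            diffs.append(abs(pe - pa))
        assert np.median(diffs) < 0.01
        assert max(diffs) < 0.02

    def test_null_p_values_uniform(self, rng):
        ps = []
        for _ in range(500):
            ps.append(rank_sum_test(rng.normal(size=20), rng.normal(size=20)).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_ties_force_asymptotic(self):
        res = rank_sum_test([1, 1, 2, 3, 4], [1, 5, 6, 7, 8])
        assert res.method == "asymptotic"
        assert res.tied


class TestMTRates:
    def _table(self, rates_a, rates_b):
        rows = []
        for cond, cells in (("ctrl", rates_a), ("ski606", rates_b)):
            for cid, rates in enumerate(cells):
                rows += [
                    {"cell_id": f"{cond}{cid}", "condition": cond, "rate_um_per_min": r}
                    for r in rates
                ]
        return pd.DataFrame(rows)

    def test_per_cell_mean_of_identical_values(self):
        tab = self._table([[1.5] * 20, [1.5] * 20], [[2.0] * 20, [2.0] * 20])
        res = mt_rate_comparison(tab, "ctrl", "ski606")
        assert np.allclose(res.cell_means_a, 1.5)
        assert res.degenerate
        assert res.mean_difference == pytest.approx(0.5)

    def test_null_rejection_rate(self, rng):
        rej = 0
        n_sim = 300
        for _ in range(n_sim):
            tab = self._table(
                [rng.normal(1.8, 0.2, 20) for _ in range(8)],
                [rng.normal(1.8, 0.2, 20) for _ in range(8)],
            )
            rej += mt_rate_comparison(tab, "ctrl", "ski606").p < 0.05
        assert rej / n_sim == pytest.approx(0.05, abs=0.04)

    def test_too_few_cells_rejected(self):
        tab = self._table([[1.5] * 20], [[2.0] * 20, [2.1] * 20])
        with pytest.raises(AnalysisError):
            mt_rate_comparison(tab, "ctrl", "ski606")


class TestMitoticTiming:
    def _events(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "cell_id",
                "condition",
                "t_condensation",
                "t_pre_anaphase",
                "t_decondensation",
            ],
        )

    def test_durations_from_timestamps(self):
        ev = self._events([("c1", "ctrl", 0.0, 30.0, 50.0)])
        out = mitotic_timing_summary(ev)
        row = out.durations.iloc[0]
        assert row["prophase_to_metaphase_min"] == 30.0
        assert row["anaphase_to_decondensation_min"] == 20.0

    def test_unordered_timestamps_rejected_with_reason(self):
        ev = self._events(
            [("c1", "ctrl", 0.0, 30.0, 50.0), ("c2", "ctrl", 10.0, 5.0, 50.0)]
        )
        out = mitotic_timing_summary(ev)
        assert len(out.rejected) == 1
        assert "ordered" in out.rejected["reason"].iloc[0]

    def test_identical_groups_compare_to_p1(self):
        rows = [(f"a{i}", "ctrl", 0.0, 20.0 + i, 40.0 + i) for i in range(5)]
        rows += [(f"b{i}", "drug", 0.0, 20.0 + i, 40.0 + i) for i in range(5)]
        out = mitotic_timing_summary(self._events(rows))
        assert out.comparisons[("ctrl", "drug", "prophase_to_metaphase_min")] == 1.0

    def test_shifted_median_detected(self, rng):
        detected = 0
        n_sim = 100
        for _ in range(n_sim):
            rows = [
                (f"a{i}", "ctrl", 0.0, t, t + 20)
                for i, t in enumerate(rng.normal(30, 5, 30))
            ]
            rows += [
                (f"b{i}", "drug", 0.0, t, t + 20)
                for i, t in enumerate(rng.normal(45, 5, 30))
            ]
            out = mitotic_timing_summary(self._events(rows))
            detected += (
                out.comparisons[("ctrl", "drug", "prophase_to_metaphase_min")] < 0.05
            )
        assert detected / n_sim >= 0.9
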