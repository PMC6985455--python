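"""Growth metrics: AUC, exponential cutoff, slopes, normalization, windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.integrate import quad

from cinsynergy import (
    SimConfig,
    WellSeries,
    compute_auc,
    compute_manual_slope,
    compute_relative_slope,
    detect_exponential_cutoff,
    metrics_table,
    normalize_to_control,
    simulate_screen,
    split_time_windows,
)
from cinsynergy.errors import GridError, InsufficientDataError, NormalizationError
from cinsynergy.growth import stitch_passage


def series(times, conf, **kw):
    return WellSeries(times=np.asarray(times, float), confluency=np.asarray(conf, float), **kw)


class TestAUC:
    def test_sum_of_constant_series(self):
        s = series(np.arange(5.0), np.full(5, 10.0))
        assert compute_auc(s, "sum") == 50.0

    def test_all_zero_series(self):
        s = series(np.arange(5.0), np.zeros(5))
        assert compute_auc(s, "sum") == 0.0
        assert compute_auc(s, "trapezoid") == 0.0

    def test_trapezoid_matches_quadrature_of_logistic(self):
        # oracle: adaptive quadrature of the closed form
        r, K, c0 = 0.05, 100.0, 5.0
        t = np.arange(0.0, 96.1, 2.0)
        f = lambda x: K / (1 + (K - c0) / c0 * np.exp(-r * x))
        s = series(t, f(t))
        exact, _ = quad(f, 0, 96, limit=200)
        assert compute_auc(s, "trapezoid") == pytest.approx(exact, rel=0.005)

    @given(
        base=hnp.arrays(
            np.float64,
            12,
            elements=st.floats(0.0, 100.0, allow_nan=False),
        ),
        bump=hnp.arrays(
            np.float64,
            12,
            elements=st.floats(0.0, 20.0, allow_nan=False),
        ),
    )
    @settings(max_examples=50, deadline=None)
    def test_auc_monotone_under_pointwise_dominance(self, base, bump):
        t = np.arange(12.0)
        lo, hi = series(t, base), series(t, base + bump)
        for method in ("sum", "trapezoid"):
            assert compute_auc(hi, method) >= compute_auc(lo, method) - 1e-9


class TestExponentialCutoff:
    def test_pure_exponential_cutoff_is_last_point(self):
        t = np.arange(0.0, 48.1, 2.0)
        s = series(t, 2.0 * np.exp(0.05 * t))
        for r2_min in (0.9, 0.99, 1.0):
            cut = detect_exponential_cutoff(s, r2_min=r2_min)
            assert cut.time_h == t[-1]
            assert not cut.low_quality

    def test_logistic_cutoff_matches_exhaustive_window_oracle(self):
        r, K, c0 = 0.1, 100.0, 1.0
        t = np.arange(0.0, 96.1, 2.0)
        c = K / (1 + (K - c0) / c0 * np.exp(-r * t))
        s = series(t, c)
        cut = detect_exponential_cutoff(s, r2_min=0.99, min_points=4)
        # oracle: brute-force R^2 of every expanding window via polyfit
        y = np.log(c / 100.0)
        best = None
        for e in range(3, t.size):
            coef = np.polyfit(t[: e + 1], y[: e + 1], 1)
            resid = y[: e + 1] - np.polyval(coef, t[: e + 1])
            ss_res = (resid**2).sum()
            ss_tot = ((y[: e + 1] - y[: e + 1].mean()) ** 2).sum()
            if 1 - ss_res / ss_tot >= 0.99:
                best = t[e]
        assert best is not None
        assert cut.time_h == best
        assert cut.time_h < t[-1]  # saturation breaks log-linearity

    def test_insufficient_positive_points(self):
        s = series([0.0, 2.0, 4.0], [1.0, 2.0, 4.0])
        with pytest.raises(InsufficientDataError):
            detect_exponential_cutoff(s, min_points=4)

    def test_flat_series_is_perfect_log_linear_fit(self):
        s = series(np.arange(6.0), np.full(6, 5.0))
        cut = detect_exponential_cutoff(s)
        assert cut.time_h == 5.0


class TestSlopes:
    def test_relative_slope_identity_and_ratio(self):
        t = np.arange(0.0, 24.1, 2.0)
        drug = series(t, 2.0 * np.exp(0.05 * t))
        ctrl = [series(t, 2.0 * np.exp(0.05 * t)) for _ in range(3)]
        assert compute_relative_slope(drug, ctrl, 24.0) == pytest.approx(1.0)
        half = series(t, 1.0 * np.exp(0.05 * t))
        assert compute_relative_slope(half, ctrl, 24.0) == pytest.approx(0.5)

    def test_relative_slope_decreases_with_drug_strength(self):
        t = np.arange(0.0, 48.1, 2.0)
        ctrl = [series(t, 2.0 * np.exp(0.05 * t))]
        rels = [
            compute_relative_slope(
                series(t, 2.0 * np.exp(0.05 * effect * t)), ctrl, 48.0
            )
            for effect in (1.0, 0.9, 0.8, 0.7, 0.6)
        ]
        assert rels[0] == pytest.approx(1.0)
        assert all(a > b for a, b in zip(rels, rels[1:]))

    def test_manual_slope_formula(self):
        t = np.array([0.0, 120.0])
        s = series(t, [10.0, 50.0])
        # 50% at day 5: -ln(0.5)/5
        assert compute_manual_slope(s, 120.0) == pytest.approx(np.log(2) / 5, rel=1e-9)

    def test_manual_slope_full_confluency_is_zero(self):
        s = series([0.0, 24.0], [10.0, 100.0])
        assert compute_manual_slope(s, 24.0) == 0.0

    def test_manual_slope_zero_confluency_rejected(self):
        s = series([0.0, 24.0], [10.0, 0.0])
        with pytest.raises(ValueError):
            compute_manual_slope(s, 24.0)

    def test_relative_manual_slope_matches_direct_evaluation(self):
        t = np.arange(0.0, 96.1, 2.0)
        drug = series(t, 2.0 * np.exp(0.03 * t))
        ctrl = series(t, 2.0 * np.exp(0.05 * t))
        got = compute_manual_slope(drug, 96.0) / compute_manual_slope(ctrl, 96.0)
        c_d, c_c = drug.confluency[-1] / 100, ctrl.confluency[-1] / 100
        assert got == pytest.approx((-np.log(c_d) / 4) / (-np.log(c_c) / 4))


class TestNormalization:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["cell_line", "drug", "bio_rep", "auc"]
        )

    def test_control_only_normalizes_to_mean_one(self):
        rec = self._records(
            [("A", "DMSO", 1, 90.0), ("A", "DMSO", 2, 110.0), ("A", "DMSO", 3, 100.0)]
        )
        out = normalize_to_control(rec)
        assert out["relative_auc"].mean() == pytest.approx(1.0)

    def test_drug_well_at_control_mean_is_one(self):
        rec = self._records(
            [("A", "DMSO", 1, 90.0), ("A", "DMSO", 2, 110.0), ("A", "drugA", 1, 100.0)]
        )
        out = normalize_to_control(rec)
        assert out.loc[out["drug"] == "drugA", "relative_auc"].iloc[0] == 1.0

    def test_missing_control_names_cell_line(self):
        rec = self._records([("A", "DMSO", 1, 90.0), ("B", "drugA", 1, 100.0)])
        with pytest.raises(NormalizationError, match="B"):
            normalize_to_control(rec)

    def test_mean_relative_auc_recovers_ground_truth(self, small_screen, small_config):
        table, gt = small_screen
        mt = metrics_table(table, vehicle="DMSO")
        got = (
            mt.groupby(["cell_line", "drug"])["relative_auc"].mean().loc[("RPE1", "drugA")]
        )
        aucs = gt.conditions.set_index(["cell_line", "drug"])["auc_noiseless"]
        truth = aucs[("RPE1", "drugA")] / aucs[("RPE1", "DMSO")]
        assert got == pytest.approx(truth, abs=0.02)

    @given(factor=st.floats(0.2, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_relative_auc_invariant_to_common_rescaling(self, factor):
        rec = self._records(
            [
                ("A", "DMSO", 1, 90.0),
                ("A", "DMSO", 2, 110.0),
                ("A", "drugA", 1, 60.0),
                ("A", "drugA", 2, 70.0),
            ]
        )
        scaled = rec.assign(auc=rec["auc"] * factor)
        out1 = normalize_to_control(rec)["relative_auc"]
        out2 = normalize_to_control(scaled)["relative_auc"]
        assert np.allclose(out1, out2)


class TestWindows:
    def _table(self, days=8.0, cadence=2.0):
        cfg = SimConfig(
            genotype_penalty={"RPE1": 1.0},
            drug_effect={"DMSO": 1.0},
            duration_h=days * 24,
            cadence_h=cadence,
            passage_day=None,
            noise_cv=0.0,
            n_bio=1,
            n_tech=1,
        )
        table, _ = simulate_screen(config=cfg)
        return table

    def test_shared_edge_split_gives_equal_durations(self):
        table = self._table()
        parts = split_time_windows(table, [4.0], edges="shared")
        assert len(parts) == 2
        spans = [p["time_h"].max() - p["time_h"].min() for _, p in parts]
        assert spans[0] == spans[1] == 96.0

    def test_halfopen_split_partitions_samples(self):
        table = self._table()
        parts = split_time_windows(table, [4.0])
        assert sum(len(p) for _, p in parts) == len(table)
        assert parts[0][1]["time_h"].max() < 96.0
        assert parts[1][1]["time_h"].min() == 96.0

    def test_boundary_beyond_data_gives_single_window(self):
        table = self._table()
        with pytest.warns(UserWarning):
            parts = split_time_windows(table, [20.0])
        assert len(parts) == 1
        pd.testing.assert_frame_equal(
            parts[0][1].reset_index(drop=True), table.reset_index(drop=True)
        )

    def test_trapezoid_auc_additive_over_shared_edge_windows(self):
        table = self._table()
        full = np.trapezoid(table["confluency_pct"], table["time_h"])
        parts = split_time_windows(table, [4.0], edges="shared")
        total = sum(
            np.trapezoid(p["confluency_pct"], p["time_h"]) for _, p in parts
        )
        assert total == pytest.approx(full, rel=1e-12)

    def test_sum_auc_additive_over_halfopen_windows(self):
        table = self._table()
        parts = split_time_windows(table, [4.0])
        assert sum(p["confluency_pct"].sum() for _, p in parts) == pytest.approx(
            table["confluency_pct"].sum()
        )


class TestMetricsTable:
    def test_sum_auc_requires_shared_grid(self, small_screen):
        table, _ = small_screen
        broken = table.iloc[1:]  # drop one observation from one well
        with pytest.raises(GridError):
            metrics_table(broken, auc_method="sum")
        # trapezoid tolerates the unequal grid
        mt = metrics_table(broken, auc_method="trapezoid", compute_slopes=False)
        assert len(mt) == table.groupby(["plate", "well"]).ngroups

    def test_stitched_passage_restores_cumulative_curve(self):
        cfg = SimConfig(
            genotype_penalty={"RPE1": 1.0},
            drug_effect={"DMSO": 1.0},
            noise_cv=0.0,
            n_bio=1,
            n_tech=1,
        )
        table, _ = simulate_screen(config=cfg)
        stitched = stitch_passage(table, 96.0, 8.0)
        post = stitched[stitched["time_h"] >= 96.0]["confluency_pct"].to_numpy()
        raw = table[table["time_h"] >= 96.0]["confluency_pct"].to_numpy()
        assert np.allclose(post, raw * 8.0)
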