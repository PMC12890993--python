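"""Recovery arithmetic, Welch t, ANOVA, report rendering."""

import numpy as np
import pytest
from scipy import stats as sps

from partiquant.conditions import DEFAULT_RECOVERY_PARAMS, MethodRecoveryParams
from partiquant.recovery import (
    DilutionChain,
    anova_oneway,
    back_calculate_mg,
    build_report,
    dilution_fold,
    fit_calibration,
    pairwise_welch,
    recovery_efficiency,
    recovery_table,
    significance_stars,
    summarize_method,
    welch_t,
)
from partiquant.synthetic import ExtractionMeasurement, generate_measurements


class TestCalibration:
    def test_exact_linear_relationship(self):
        levels = [0.01, 0.05, 0.10, 0.50, 2.00]
        curve = fit_calibration(levels, [2 * x for x in levels])
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r2 == pytest.approx(1.0)

    def test_two_points_interpolate_exactly(self):
        curve = fit_calibration([1.0, 3.0], [5.0, 9.0])
        assert curve.slope * 1.0 + curve.intercept == pytest.approx(5.0)
        assert curve.slope * 3.0 + curve.intercept == pytest.approx(9.0)

    def test_noisy_slope_recovery(self):
        """Across seeds the fitted slope is unbiased around the truth."""
        levels = np.array([0.01, 0.05, 0.10, 0.50, 2.00])
        slopes = []
        rng = np.random.default_rng(0)
        for _ in range(100):
            responses = 1.7 * levels + rng.normal(0, 0.02, levels.size)
            slopes.append(fit_calibration(levels, responses).slope)
        assert np.mean(slopes) == pytest.approx(1.7, abs=0.02)

    def test_identical_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([1.0, 1.0], [2.0, 3.0])


class TestDilutionAndBackCalculation:
    def test_protocol_dilution_is_1000_fold(self):
        chain = DilutionChain(aliquot_volume_ul=25, final_volume_ml=25, flask_volume_ml=50)
        assert dilution_fold(chain) == pytest.approx(1000.0)

    @pytest.mark.parametrize(
        "aliquot_ul,final_ml,expected",
        [(1000, 1, 1), (10, 1, 100), (25, 25, 1000)],
    )
    def test_fold_arithmetic(self, aliquot_ul, final_ml, expected):
        chain = DilutionChain(aliquot_ul, final_ml, 50)
        assert dilution_fold(chain) == pytest.approx(expected)

    def test_back_calculation_filtrate_flask(self):
        chain = DilutionChain(25, 25, 50)
        assert back_calculate_mg(0.65, chain) == pytest.approx(32.5)

    def test_back_calculation_cotton_flask(self):
        chain = DilutionChain(25, 25, 10)
        assert back_calculate_mg(0.92, chain) == pytest.approx(9.2)

    def test_zero_concentration_zero_mass(self):
        assert back_calculate_mg(0.0, DilutionChain(25, 25, 50)) == 0.0

    def test_round_trip_recovers_known_mass(self):
        """Forward-simulated vial concentration inverts to the exact mass."""
        chain = DilutionChain(25, 25, 50)
        for mg in (0.5, 7.7, 32.5, 44.9):
            vial = (mg / chain.flask_volume_ml) * 1000.0 / chain.fold  # ug/ml after dilution
            assert back_calculate_mg(vial, chain) == pytest.approx(mg, rel=1e-12)

    def test_out_of_range_concentration_warns(self):
        curve = fit_calibration([0.01, 2.0], [0.01, 2.0])
        with pytest.warns(UserWarning, match="calibration range"):
            back_calculate_mg(5.0, DilutionChain(25, 25, 50), calibration=curve)

    def test_invalid_volumes_rejected(self):
        with pytest.raises(ValueError):
            DilutionChain(0, 25, 50)


class TestRecoveryEfficiency:
    def test_reported_protocol_a_value(self):
        assert recovery_efficiency(32.5, 7.7) == pytest.approx(89.3)

    def test_zero_and_half(self):
        assert recovery_efficiency(0.0, 0.0) == 0.0
        assert recovery_efficiency(22.5, 0.0) == pytest.approx(50.0)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            recovery_efficiency(-1.0, 0.0)


class TestSummarizeMethod:
    def test_constant_replicates(self):
        ms = [ExtractionMeasurement("D", i, 31.3, 5.2) for i in range(1, 4)]
        s = summarize_method(ms)
        assert s.sum_mg == pytest.approx(36.5)
        assert s.efficiency_pct == pytest.approx(81.1, abs=0.05)
        assert s.sd_extracted_mg == 0.0

    def test_single_replicate_sd_undefined(self):
        s = summarize_method([ExtractionMeasurement("A", 1, 30.0, 5.0)])
        assert s.n == 1 and np.isnan(s.sd_extracted_mg)

    def test_large_sample_recovers_generator_parameters(self):
        """10^4 replicates reproduce the configured means/SDs within 1%."""
        params = {"A": DEFAULT_RECOVERY_PARAMS["A"]}
        ms = generate_measurements(params, n={"A": 10_000}, seed=4)
        s = summarize_method(ms)
        assert s.mean_extracted_mg == pytest.approx(32.5, rel=0.01)
        assert s.sd_extracted_mg == pytest.approx(13.2, rel=0.035)
        assert s.mean_remaining_mg == pytest.approx(7.7, rel=0.01)

    def test_mixed_methods_rejected(self):
        ms = [ExtractionMeasurement("A", 1, 1, 1), ExtractionMeasurement("B", 1, 1, 1)]
        with pytest.raises(ValueError):
            summarize_method(ms)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_method([])


class TestWelch:
    def test_identical_groups_null(self):
        res = welch_t(5.0, 1.0, 4, 5.0, 1.0, 4)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert res.stars == ""

    def test_reported_sums_comparison(self):
        """Protocols D vs B total recovered: |t|~2.40, df~4.0, p~0.075."""
        res = welch_t(36.5, 2.3, 3, 41.1, 2.4, 3)
        assert abs(res.statistic) == pytest.approx(2.40, abs=0.01)
        assert res.degrees_of_freedom == pytest.approx(4.0, abs=0.02)
        assert res.p_value == pytest.approx(0.075, abs=0.005)

    def test_symmetry_under_group_swap(self):
        a = welch_t(10, 2, 5, 12, 3, 7)
        b = welch_t(12, 3, 7, 10, 2, 5)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_matches_scipy_from_stats_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            m1, m2 = rng.normal(0, 5, 2)
            s1, s2 = rng.uniform(0.5, 4, 2)
            n1, n2 = rng.integers(2, 12, 2)
            mine = welch_t(m1, s1, int(n1), m2, s2, int(n2))
            t, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
            assert mine.statistic == pytest.approx(t)
            assert mine.p_value == pytest.approx(p)

    def test_equal_variance_limit_matches_pooled_t(self):
        """With equal SDs and n, Welch coincides with the classical t."""
        mine = welch_t(3.0, 1.5, 6, 4.2, 1.5, 6)
        t, p = sps.ttest_ind_from_stats(3.0, 1.5, 6, 4.2, 1.5, 6, equal_var=True)
        assert mine.statistic == pytest.approx(t)
        assert mine.p_value == pytest.approx(p, rel=1e-6)
        assert mine.degrees_of_freedom == pytest.approx(10.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            welch_t(1, 0, 3, 1, 0, 3)
        with pytest.raises(ValueError):
            welch_t(1, 1, 1, 2, 1, 3)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = anova_oneway([[1.0, 2.0, 3.0]] * 3)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_sum_of_squares(self):
        groups = [[1, 2, 3], [2, 3, 4], [9, 10, 11]]
        # brute-force SS decomposition
        allv = np.concatenate(groups).astype(float)
        grand = allv.mean()
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
        f_oracle = (ssb / 2) / (ssw / 6)
        res = anova_oneway(groups)
        assert res.statistic == pytest.approx(f_oracle)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            groups = [rng.normal(rng.uniform(-1, 1), 1.0, rng.integers(3, 8)) for _ in range(4)]
            res = anova_oneway(groups)
            f, p = sps.f_oneway(*groups)
            assert res.statistic == pytest.approx(f)
            assert res.p_value == pytest.approx(p)

    def test_shift_invariance_and_scale(self):
        groups = [[1.0, 2.0, 4.0], [3.0, 5.0, 6.0], [2.0, 2.5, 3.0]]
        base = anova_oneway(groups)
        shifted = anova_oneway([[x + 100 for x in g] for g in groups])
        scaled = anova_oneway([[x * 7 for x in g] for g in groups])
        assert shifted.statistic == pytest.approx(base.statistic)
        assert scaled.statistic == pytest.approx(base.statistic)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [2.0, 3.0]])
        with pytest.raises(ValueError):
            anova_oneway([[1.0, 2.0]])


class TestStarsAndReport:
    @pytest.mark.parametrize(
        "p,stars",
        [(0.0005, "***"), (0.001, "**"), (0.005, "**"), (0.01, "*"), (0.049, "*"),
         (0.05, ""), (0.2, "")],
    )
    def test_strict_threshold_mapping(self, p, stars):
        assert significance_stars(p) == stars

    def test_recovery_table_matches_reported_rows(self):
        """Summaries built from the reported stats round-trip the table."""
        summaries = {
            m: summarize_method(
                [
                    ExtractionMeasurement(m, 1, p.extracted_mean_mg, p.remaining_mean_mg),
                    ExtractionMeasurement(m, 2, p.extracted_mean_mg, p.remaining_mean_mg),
                ]
            )
            for m, p in DEFAULT_RECOVERY_PARAMS.items()
        }
        table = recovery_table(summaries)
        assert list(table["method"]) == ["A", "B", "C", "D"]
        a = table[table["method"] == "A"].iloc[0]
        assert a["sum_mg"] == pytest.approx(40.2)
        assert a["efficiency_pct"] == pytest.approx(89.3)
        d = table[table["method"] == "D"].iloc[0]
        assert d["sum_mg"] == pytest.approx(36.5)

    def test_build_report_structure(self):
        ms = generate_measurements(DEFAULT_RECOVERY_PARAMS, seed=0)
        summaries = {
            m: summarize_method([x for x in ms if x.method == m]) for m in "ABCD"
        }
        report = build_report(summaries, pairwise_welch(summaries))
        assert set(report) >= {"recovery", "pairwise", "markdown"}
        assert len(report["recovery"]) == 4
        assert "| method |" in report["markdown"]
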