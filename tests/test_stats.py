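"""Cell means, anticipation statistic, learning curve, RM-ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest

from nyctinast.motion import FrameSeries, WateringEvent, exclusion_mask
from nyctinast.schedule import CONDITIONS, INTERVALS, build_phase
from nyctinast.stats import (
    CellTable,
    StatsError,
    cell_means,
    error_df,
    fit_log_curve,
    motion_difference,
    partial_eta_sq,
    rm_anova,
    simple_effects,
    stratify_by_day_length,
)
from nyctinast.synthdata import SimParams, inject_artifacts, simulate_motion

from conftest import COARSE_DT, simulate_cells


def table_from_grid(values, cycles, day_length=24.0):
    """CellTable from a {(condition, interval): per-cycle value} mapping."""
    rows = []
    for c in cycles:
        for cond in CONDITIONS:
            for iv in INTERVALS:
                v = values((c, cond, iv)) if callable(values) else values[(cond, iv)]
                rows.append(dict(cycle=c, condition=cond, interval=iv, mean=v,
                                 n_frames=10, day_length_h=day_length))
    return CellTable(pd.DataFrame(rows))


class TestCellMeans:
    def test_constant_series_fills_every_cell_with_one(self, phase2_schedule):
        ts = phase2_schedule.frame_times(COARSE_DT)
        series = FrameSeries(ts, np.ones(len(ts)), np.ones(len(ts), bool), COARSE_DT)
        cells = cell_means(series, phase2_schedule)
        assert cells.data["mean"].to_numpy() == pytest.approx(np.ones(9 * 6))
        assert (cells.data["n_frames"] > 0).all()

    def test_prelight_frames_separated_from_others(self, phase2_schedule):
        ts = phase2_schedule.frame_times(COARSE_DT)
        labels = phase2_schedule.label_times(ts)
        motion = np.where(labels["interval"] == "pre-light", 2.0, 1.0)
        series = FrameSeries(ts, motion, np.ones(len(ts), bool), COARSE_DT)
        cells = cell_means(series, phase2_schedule)
        pre = cells.data["interval"] == "pre-light"
        assert cells.data.loc[pre, "mean"].to_numpy() == pytest.approx(2.0)
        assert cells.data.loc[~pre, "mean"].to_numpy() == pytest.approx(1.0)

    def test_cells_without_valid_frames_flagged_missing(self, phase2_schedule):
        ts = phase2_schedule.frame_times(COARSE_DT)
        labels = phase2_schedule.label_times(ts)
        valid = ~((labels["cycle"] == 2) & (labels["condition"] == "Dark")).to_numpy()
        series = FrameSeries(ts, np.ones(len(ts)), valid, COARSE_DT)
        cells = cell_means(series, phase2_schedule)
        gone = cells.data[(cells.data["cycle"] == 2) & (cells.data["condition"] == "Dark")]
        assert gone["mean"].isna().all()
        assert (gone["n_frames"] == 0).all()

    def test_weighted_cells_reconstruct_global_mean(self, phase2_schedule):
        rng = np.random.default_rng(4)
        ts = phase2_schedule.frame_times(COARSE_DT)
        motion = rng.gamma(2.0, 0.5, size=len(ts))
        valid = rng.random(len(ts)) > 0.1
        series = FrameSeries(ts, motion, valid, COARSE_DT)
        cells = cell_means(series, phase2_schedule)
        assert cells.weighted_mean() == pytest.approx(motion[valid].mean(), abs=1e-12)

    def test_artifact_injection_plus_exclusion_is_lossless(self, phase2_schedule):
        params = SimParams(seed=11)
        series, _ = simulate_motion(params, phase2_schedule, COARSE_DT)
        events = [WateringEvent(10 * 3600.0, 10 * 3600.0 + 300.0)]
        corrupted = inject_artifacts(series, phase2_schedule,
                                     watering_events=events, keyframe_period=250)
        keep = exclusion_mask(series.timestamps_s, schedule=phase2_schedule,
                              watering_events=events, keyframe_period_frames=250)
        clean = cell_means(series.mask(keep), phase2_schedule)
        fixed = cell_means(corrupted.mask(keep), phase2_schedule)
        assert fixed.data["mean"].to_numpy() == pytest.approx(
            clean.data["mean"].to_numpy(), abs=1e-9
        )


class TestMotionDifference:
    def test_equal_prelight_means_give_zero(self):
        t = table_from_grid({(c, i): 1.0 for c in CONDITIONS for i in INTERVALS}, [1])
        assert motion_difference(t, 1) == 0.0

    def test_phase1_printed_prelight_means(self):
        """(0.890 + 0.898)/2 - 0.840 = 0.054."""
        vals = {(c, i): 1.0 for c in CONDITIONS for i in INTERVALS}
        vals[("Light1", "pre-light")] = 0.890
        vals[("Light2", "pre-light")] = 0.898
        vals[("Dark", "pre-light")] = 0.840
        t = table_from_grid(vals, [1])
        assert motion_difference(t, 1) == pytest.approx(0.054)

    def test_antisymmetry_under_light_dark_swap(self):
        vals = {(c, i): 1.0 for c in CONDITIONS for i in INTERVALS}
        vals[("Light1", "pre-light")] = vals[("Light2", "pre-light")] = 1.2
        vals[("Dark", "pre-light")] = 0.8
        swapped = dict(vals)
        swapped[("Light1", "pre-light")] = swapped[("Light2", "pre-light")] = 0.8
        swapped[("Dark", "pre-light")] = 1.2
        d1 = motion_difference(table_from_grid(vals, [1]), 1)
        d2 = motion_difference(table_from_grid(swapped, [1]), 1)
        assert d1 == pytest.approx(-d2)

    def test_constant_shift_invariance(self):
        vals = {(c, i): 0.9 for c in CONDITIONS for i in INTERVALS}
        vals[("Dark", "pre-light")] = 0.7
        base = motion_difference(table_from_grid(vals, [1]), 1)
        shifted = {k: v + 5.0 for k, v in vals.items()}
        assert motion_difference(table_from_grid(shifted, [1]), 1) == pytest.approx(base)

    def test_missing_cell_propagates(self):
        vals = {(c, i): 1.0 for c in CONDITIONS for i in INTERVALS}
        vals[("Dark", "pre-light")] = float("nan")
        t = table_from_grid(vals, [1])
        assert math.isnan(motion_difference(t, 1))


class TestLearningCurve:
    def test_exact_recovery_of_phase1_equation(self):
        c = np.arange(1, 24)
        d = 0.10 * np.log(c) - 0.18
        fit = fit_log_curve(d, cycles=c)
        assert fit.slope == pytest.approx(0.10, abs=1e-10)
        assert fit.intercept == pytest.approx(-0.18, abs=1e-10)
        assert fit.rsquared == pytest.approx(1.0, abs=1e-10)

    def test_exact_recovery_of_phase2_equation(self):
        c = np.arange(1, 7)
        d = 0.05 * np.log(c) + 0.01
        fit = fit_log_curve(d, cycles=c)
        assert fit.params == pytest.approx((0.05, 0.01), abs=1e-10)
        assert fit.rsquared == pytest.approx(1.0, abs=1e-10)

    def test_constant_response_has_undefined_r2(self):
        fit = fit_log_curve(np.full(5, 0.3), cycles=np.arange(1, 6))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(fit.rsquared)

    def test_single_cycle_rejected(self):
        with pytest.raises(StatsError):
            fit_log_curve([0.1], cycles=[1])
        with pytest.raises(StatsError):
            fit_log_curve([0.1, 0.2], cycles=[3, 3])

    def test_log_base_configurable(self):
        c = np.arange(1, 11)
        d = 0.2 * np.log10(c) + 0.05
        fit = fit_log_curve(d, cycles=c, log_base=10)
        assert fit.params == pytest.approx((0.2, 0.05), abs=1e-10)

    def test_series_input_uses_index_as_cycles(self):
        s = pd.Series(0.10 * np.log(np.arange(1, 24)) - 0.18,
                      index=np.arange(1, 24))
        assert fit_log_curve(s).slope == pytest.approx(0.10, abs=1e-10)


class TestEffectSizeHelpers:
    @pytest.mark.parametrize(
        "ss, ss_res, expected",
        [(0.1284, 0.4867, 0.209), (0.07801, 0.00372, 0.954), (0.0, 1.0, 0.0)],
    )
    def test_partial_eta_sq(self, ss, ss_res, expected):
        assert round(partial_eta_sq(ss, ss_res), 3) == expected

    def test_partial_eta_sq_undefined_for_double_zero(self):
        with pytest.raises(StatsError):
            partial_eta_sq(0.0, 0.0)

    def test_error_df_bookkeeping(self):
        assert error_df(22, 2) == 42
        assert error_df(22, 4) == 84


class TestRmAnova:
    def test_row_identities_hold_exactly(self, phase1_schedule):
        cells, _ = simulate_cells(phase1_schedule, seed=7)
        res = rm_anova(cells)
        t = res.anova_table
        assert t["mean_sq"].to_numpy() * t["df"].to_numpy() == pytest.approx(
            t["sum_sq"].to_numpy(), abs=1e-12
        )
        resid_ms = {}
        current = []
        for _, row in t.iterrows():
            if row["Source"] == "Residual":
                for r in current:
                    assert r["F"] == pytest.approx(r["mean_sq"] / row["mean_sq"], rel=1e-12)
                    eta = r["sum_sq"] / (r["sum_sq"] + row["sum_sq"])
                    assert r["partial_eta_sq"] == pytest.approx(eta, rel=1e-12)
                    assert 0 <= r["partial_eta_sq"] <= 1
                current = []
            else:
                current.append(row)

    def test_phase1_design_degrees_of_freedom(self, phase1_schedule):
        """23 cycles, cycle covariate: residual dfs 42/42/84."""
        cells, _ = simulate_cells(phase1_schedule, seed=1)
        t = rm_anova(cells).anova_table
        assert list(t.loc[t["Source"] == "Residual", "df"]) == [42, 42, 84]

    def test_phase3_design_degrees_of_freedom(self):
        """30 cycles, cycle + day-length covariates: residual dfs 54/54/108."""
        sched = build_phase(3, 30, seed=5)
        cells, _ = simulate_cells(sched, seed=2)
        t = rm_anova(cells, covariates=("cycle", "day_length")).anova_table
        assert list(t.loc[t["Source"] == "Residual", "df"]) == [54, 54, 108]
        assert {"Time-of-day × day length", "Day condition × day length"} <= set(t["Source"])

    def test_matches_pingouin_without_covariates(self):
        """Independent oracle: classical two-way RM-ANOVA."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        t = table_from_grid(lambda key: rng.normal(1.0, 0.1), cycles=range(1, 11))
        from nyctinast.stats import RepeatedMeasuresAnova

        mine = RepeatedMeasuresAnova(t, covariates=()).fit().anova_table
        theirs = pg.rm_anova(
            data=t.data.rename(columns={"mean": "y"}), dv="y",
            within=["condition", "interval"], subject="cycle", detailed=True,
        ).set_index("Source")
        for mine_name, pg_name in [
            ("Day condition", "condition"),
            ("Time-of-day", "interval"),
            ("Time-of-day × Day condition", "condition * interval"),
        ]:
            row = mine[mine["Source"] == mine_name].iloc[0]
            ref = theirs.loc[pg_name]
            assert row["sum_sq"] == pytest.approx(ref["SS"], rel=1e-9)
            assert row["F"] == pytest.approx(ref["F"], rel=1e-9)
            assert row["p"] == pytest.approx(ref["p_unc"], rel=1e-9)

    def test_too_few_units_rejected(self):
        t = table_from_grid({(c, i): 1.0 for c in CONDITIONS for i in INTERVALS}, [1])
        with pytest.raises(StatsError):
            rm_anova(t)

    def test_incomplete_cycles_dropped_listwise(self, phase2_schedule):
        cells, _ = simulate_cells(phase2_schedule, seed=9)
        data = cells.data.copy()
        data.loc[(data["cycle"] == 3) & (data["condition"] == "Dark"), "mean"] = np.nan
        res = rm_anova(CellTable(data))
        assert res.n_units == 5
        assert res.dropped_cycles == (3,)


class TestSimpleEffects:
    def test_restricted_to_one_interval(self, phase1_schedule):
        cells, _ = simulate_cells(phase1_schedule, seed=3)
        res = simple_effects(cells, "pre-light")
        assert list(res.anova_table["Source"]) == [
            "Day condition", "Day condition × cycle", "Residual",
        ]
        assert list(res.anova_table["df"]) == [2, 2, 42]

    def test_single_cycle_rejected(self):
        t = table_from_grid({(c, i): 1.0 for c in CONDITIONS for i in INTERVALS}, [1])
        with pytest.raises(StatsError):
            simple_effects(t, "pre-light")

    def test_unknown_interval_rejected(self, phase1_schedule):
        cells, _ = simulate_cells(phase1_schedule, seed=3)
        with pytest.raises(StatsError):
            simple_effects(cells, "midnight")

    def test_builtin_condition_by_cycle_effect_detected(self, phase1_schedule):
        """An anticipation curve in the generator shows up as the
        condition x cycle interaction of the pre-light simple effects."""
        detected = 0
        for seed in range(15):
            cells, _ = simulate_cells(phase1_schedule, seed=seed)
            res = simple_effects(cells, "pre-light")
            detected += res.pvalue("Day condition × cycle") < 0.05
        assert detected >= 12  # >= 80%

    def test_null_interval_f_consistent_with_null(self):
        """Under a null generator the p-values are uniform (KS check)."""
        from scipy import stats as sps

        sched = build_phase(1, 8)
        pvals = []
        for seed in range(60):
            cells, _ = simulate_cells(
                sched, capture_interval_s=240.0, seed=seed,
                a_true=0.0, b_true=0.0, light_boost=0.0, spike_height=0.0,
            )
            pvals.append(simple_effects(cells, "pre-light").pvalue("Day condition"))
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestStratifyByDayLength:
    def test_all_in_band_when_constant_20h(self):
        d = pd.Series([0.1, 0.2, 0.3], index=[1, 2, 3])
        n = pd.Series([20.0, 20.0, 20.0], index=[1, 2, 3])
        strat = stratify_by_day_length(d, n)
        assert strat["in_band"].n_cycles == 3
        assert strat["out_of_band"].n_cycles == 0
        assert math.isnan(strat["out_of_band"].mean_difference)

    def test_band_inclusive_at_both_ends(self):
        d = pd.Series([0.1, 0.2, 0.3, 0.4], index=[1, 2, 3, 4])
        n = pd.Series([12.0, 24.0, 10.0, 26.0], index=[1, 2, 3, 4])
        strat = stratify_by_day_length(d, n)
        assert strat["in_band"].cycles == (1, 2)
        assert strat["out_of_band"].cycles == (3, 4)

    def test_in_band_gets_learning_curve_fit(self):
        c = np.arange(1, 11)
        d = pd.Series(0.1 * np.log(c) - 0.18, index=c)
        n = pd.Series(20.0, index=c)
        strat = stratify_by_day_length(d, n)
        assert strat["in_band"].fit is not None
        assert strat["in_band"].fit.slope == pytest.approx(0.1, abs=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(StatsError):
            stratify_by_day_length(pd.Series(dtype=float), pd.Series(dtype=float))

    def test_generator_band_effect_separates_groups(self):
        """Generator applies anticipation only in-band: in-band differences
        positive, out-of-band centred at zero (sign test over seeds)."""
        from scipy.stats import binomtest

        in_pos = 0
        n_seeds = 20
        for seed in range(n_seeds):
            sched = build_phase(3, 8, seed=100 + seed)
            cells, _ = simulate_cells(sched, seed=seed, b_true=0.08)
            strat = stratify_by_day_length(cells.motion_differences(),
                                           cells.day_lengths())
            if strat["in_band"].n_cycles and strat["in_band"].mean_difference > 0:
                in_pos += 1
        assert binomtest(in_pos, n_seeds, 0.5, alternative="greater").pvalue < 0.05
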