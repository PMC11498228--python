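"""Drinking-analysis pipeline tests: fluids, binning, preference, intake."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

import lickometry as lk
from lickometry import analysis
from lickometry.analysis import (
    UnassignedBoutError,
    UndefinedPreferenceError,
    assign_fluids,
    bin_hourly,
    daily_summary,
    estimate_volume_ul,
    ethanol_intake_gkg,
    moving_average,
    preference_scalar,
    preference_series,
)
from lickometry.events import Bout, Side
from lickometry.io import iso_to_ms

from _oracles import oracle_moving_average


def make_bout(start, side=Side.LEFT, size=10, animal="M0"):
    duration, contact = 1000, 300
    return Bout(
        side=side,
        start=start,
        end=start + duration,
        size=size,
        bout_duration=duration,
        total_lick_duration=contact,
        lick_frequency=size / (duration / 1000),
        est_ili=(duration - contact) / size,
        animal=animal,
    )


@pytest.fixture(scope="module")
def labeled_week(week_plan, week_results):
    return assign_fluids([r.bout for r in week_results], week_plan)


class TestAssignFluids:
    def test_label_follows_side_within_period(self, week_plan):
        t = week_plan.start + 3_600_000
        etoh_side = next(
            s for s in Side if week_plan.periods[0].fluid_for(s).ethanol_pct > 0
        )
        (b,) = assign_fluids([make_bout(t, side=etoh_side)], week_plan)
        assert b.fluid == "ethanol"

    def test_labels_flip_at_swap_boundary(self, swap_plan):
        # same physical side, periods 1 and 2: ethanol swaps sides
        p1, p2 = swap_plan.periods[1], swap_plan.periods[2]
        side = next(s for s in Side if p1.fluid_for(s).ethanol_pct > 0)
        before = make_bout(p2.start - 7_200_000, side=side)
        after = make_bout(p2.start + 7_200_000, side=side)
        lab_before, lab_after = assign_fluids([before, after], swap_plan)
        assert lab_before.fluid == "ethanol"
        assert lab_after.fluid == "water"

    def test_interval_containment_matches_join_oracle(self, swap_plan, rng):
        starts = rng.integers(swap_plan.start, swap_plan.end, 300)
        sides = [Side.LEFT if rng.random() < 0.5 else Side.RIGHT for _ in starts]
        bouts = [make_bout(int(t), side=s) for t, s in sorted(zip(starts, sides), key=lambda x: x[0])]
        labeled = assign_fluids(bouts, swap_plan)
        for b in labeled:
            period = next(
                p for p in swap_plan.periods if p.start <= b.start < p.end
            )
            assert b.fluid == period.fluid_for(b.side).fluid

    def test_bout_outside_all_periods_errors_with_indices(self, week_plan):
        inside = make_bout(week_plan.start + 1000)
        outside = make_bout(week_plan.end + 1000)
        with pytest.raises(UnassignedBoutError) as err:
            assign_fluids([inside, outside], week_plan)
        assert err.value.indices == [1]


class TestBinHourly:
    def test_single_bout_lands_in_its_clock_bin(self, week_plan):
        t = iso_to_ms("2024-03-02 13:05:00")
        b = make_bout(t, side=Side.LEFT, size=47)
        hourly = bin_hourly(assign_fluids([b], week_plan), week_plan)
        hit = hourly[hourly.lick_count > 0]
        assert len(hit) == 1
        assert hit.iloc[0].bin_start == iso_to_ms("2024-03-02 13:00:00")
        assert hit.iloc[0].lick_count == 47
        assert hit.iloc[0].bout_count == 1

    def test_no_bouts_gives_all_zero_grid(self, week_plan):
        hourly = bin_hourly([], week_plan, animals=["M0"])
        assert (hourly.lick_count == 0).all()
        assert len(hourly) == 7 * 24 * len(week_plan.fluids())

    def test_dark_flag_matches_plan(self, week_plan, labeled_week):
        hourly = bin_hourly(labeled_week, week_plan)
        assert (hourly.is_dark == hourly.bin_start.map(week_plan.is_dark)).all()


def test_hourly_and_daily_conserve_licks(week_plan, labeled_week):
    df = analysis.bouts_to_frame(labeled_week)
    truth_totals = df.groupby(["animal", "fluid"])["size"].sum()
    hourly = bin_hourly(labeled_week, week_plan)
    hourly_totals = hourly.groupby(["animal", "fluid"])["lick_count"].sum()
    daily = daily_summary(labeled_week, week_plan)
    daily_totals = daily.groupby(["animal", "fluid"])["total_licks"].sum()
    for key, total in truth_totals.items():
        assert hourly_totals[key] == total
        assert daily_totals[key] == total


class TestPreference:
    def test_raw_bin_preference(self):
        assert preference_scalar(75, 25) == 0.75
        assert preference_scalar(300, 100) == 0.75
        assert preference_scalar(0, 500) == 0.0
        assert preference_scalar(200, 200) == 0.5

    def test_undefined_preference(self):
        with pytest.raises(UndefinedPreferenceError):
            preference_scalar(0, 0)
        with pytest.raises(ValueError):
            preference_scalar(-1, 5)

    def test_smoothing_constant_series_is_identity(self):
        x = np.full(48, 0.5)
        assert moving_average(x, 12) == pytest.approx(x)

    def test_smoothing_step_series_matches_windowed_mean_oracle(self):
        x = np.array([0.0] * 24 + [1.0] * 24)
        got = moving_average(x, 12)
        assert got == pytest.approx(oracle_moving_average(x, 12), nan_ok=True)

    def test_smoothing_skips_missing_bins(self):
        x = np.array([0.4, np.nan, 0.6, np.nan, np.nan])
        got = moving_average(x, 3)
        assert got == pytest.approx(oracle_moving_average(x, 3), nan_ok=True)

    def test_window_must_be_positive(self, week_plan, labeled_week):
        hourly = bin_hourly(labeled_week, week_plan)
        with pytest.raises(ValueError):
            preference_series(hourly, window=0)

    def test_series_bounded_and_smoothed_in_unit_interval(self, week_plan, labeled_week):
        hourly = bin_hourly(labeled_week, week_plan)
        pref = preference_series(hourly)
        finite = pref.preference_smoothed.dropna()
        assert ((finite >= 0) & (finite <= 1)).all()

    def test_scalar_within_binomial_interval_of_true_p(
        self, week_session, cage_profiles, labeled_week
    ):
        for prof in cage_profiles:
            mine = [b for b in labeled_week if b.animal == prof.tag]
            n = len(mine)
            assert n >= 500
            pref = preference_scalar(
                sum(b.size for b in mine if b.fluid == "ethanol"),
                sum(b.size for b in mine if b.fluid == "water"),
            )
            lo = binom.ppf(0.005, n, prof.ethanol_preference) / n
            hi = binom.ppf(0.995, n, prof.ethanol_preference) / n
            assert lo <= pref <= hi


class TestIntake:
    def test_720_licks_is_about_one_ml(self):
        assert estimate_volume_ul(720) == pytest.approx(1008.0)

    def test_volume_linear_and_monotone(self):
        assert estimate_volume_ul(0) == 0.0
        assert estimate_volume_ul(1000) == pytest.approx(1400.0)
        assert estimate_volume_ul(2000) == pytest.approx(2 * estimate_volume_ul(1000))
        with pytest.raises(ValueError):
            estimate_volume_ul(-1)

    def test_gkg_formula(self):
        # 1 ml of 10% v/v for a 25 g mouse: 1 * 0.1 * 0.789 / 0.025
        assert ethanol_intake_gkg(1.0, 10, 25) == pytest.approx(3.156)
        assert ethanol_intake_gkg(0.0, 10, 25) == 0.0
        assert ethanol_intake_gkg(2.0, 10, 25) == pytest.approx(2 * 3.156)
        with pytest.raises(ValueError):
            ethanol_intake_gkg(1.0, 10, 0)


class TestDailySummary:
    def test_two_bouts_single_day(self, week_plan):
        t = week_plan.start + 3_600_000
        bouts = assign_fluids(
            [make_bout(t, size=10), make_bout(t + 10_000, size=30)], week_plan
        )
        daily = daily_summary(bouts, week_plan)
        row = daily[(daily.total_licks > 0)].iloc[0]
        assert row.total_licks == 40
        assert row.bout_number == 2
        assert row.mean_bout_size == pytest.approx(20.0)

    def test_day_without_bouts_has_absent_means(self, week_plan):
        t = week_plan.start + 3_600_000
        daily = daily_summary(
            assign_fluids([make_bout(t, size=10)], week_plan), week_plan
        )
        empty = daily[daily.bout_number == 0]
        assert len(empty) > 0
        assert empty.mean_bout_size.isna().all()

    def test_matches_groupby_oracle(self, week_plan, labeled_week):
        daily = daily_summary(labeled_week, week_plan)
        df = analysis.bouts_to_frame(labeled_week)
        df["day"] = df["start"].map(week_plan.day_index)
        expected = df.groupby(["animal", "day", "fluid"]).agg(
            total_licks=("size", "sum"),
            bout_number=("size", "count"),
            mean_bout_size=("size", "mean"),
            mean_bout_duration_ms=("bout_duration_ms", "mean"),
            mean_lick_frequency_hz=("lick_frequency_hz", "mean"),
            mean_est_ili_ms=("est_ili_ms", "mean"),
        )
        got = daily.set_index(["animal", "day", "fluid"])
        for key, exp_row in expected.iterrows():
            row = got.loc[key]
            for col in expected.columns:
                assert row[col] == pytest.approx(exp_row[col]), (key, col)
        # cells absent from the oracle are the zero-bout grid entries
        zero = got.drop(index=expected.index)
        assert (zero.bout_number == 0).all()
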