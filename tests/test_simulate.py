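"""Cage-simulator tests: reproducibility, recoverability, distributions."""

import numpy as np
import pytest
from scipy.stats import poisson

import lickometry as lk
from lickometry.analysis import UL_PER_LICK
from lickometry.events import Side, detect_bouts
from lickometry.simulate import (
    SimConfigError,
    corrupt_governing_scan,
    corrupt_stream,
    match_truth,
    recover_bouts,
    simulate_session,
)


class TestConfig:
    def test_zero_rates_give_empty_session(self, week_plan):
        prof = lk.MouseProfile(tag="M0", dark_bout_rate=0.0, light_bout_rate=0.0)
        truth = simulate_session([prof], week_plan, seed=1)
        assert truth.bouts == ()
        assert truth.scans == ()
        assert all(m.volume_ml == 0.0 for m in truth.measurements)

    def test_infeasible_lick_timing_rejected(self, week_plan):
        prof = lk.MouseProfile(tag="M0", ioi_mean_ms=1200.0)
        with pytest.raises(SimConfigError):
            simulate_session([prof], week_plan, seed=1)

    def test_no_profiles_rejected(self, week_plan):
        with pytest.raises(SimConfigError):
            simulate_session([], week_plan, seed=1)

    def test_duplicate_tags_rejected(self, week_plan):
        profs = [lk.MouseProfile(tag="M0"), lk.MouseProfile(tag="M0")]
        with pytest.raises(SimConfigError):
            simulate_session(profs, week_plan, seed=1)


class TestReproducibility:
    def test_same_seed_same_streams(self, week_plan, cage_profiles):
        a = simulate_session(cage_profiles, week_plan, seed=5)
        b = simulate_session(cage_profiles, week_plan, seed=5)
        assert a.bouts == b.bouts
        assert a.scans == b.scans
        assert a.measurements == b.measurements

    def test_different_seed_different_streams(self, week_plan, cage_profiles):
        a = simulate_session(cage_profiles, week_plan, seed=5)
        b = simulate_session(cage_profiles, week_plan, seed=6)
        assert a.bouts != b.bouts


class TestRecoverability:
    def test_margin_mode_bouts_recovered_exactly(self, week_session, week_results):
        truth = week_session
        assert len(week_results) == len(truth.bouts)
        got = sorted((r.bout.side, r.bout.start, r.bout.size) for r in week_results)
        expected = sorted((b.side, b.start, b.size) for b in truth.bouts)
        assert got == expected

    def test_degenerate_preference_all_bouts_on_ethanol_side(self, week_plan):
        prof = lk.MouseProfile(tag="M0", ethanol_preference=1.0, dark_bout_rate=4.0)
        truth = simulate_session([prof], week_plan, seed=9)
        assert len(truth.bouts) > 50
        assert all(b.fluid == "ethanol" for b in truth.bouts)
        results = recover_bouts(truth)
        report = lk.attribution_accuracy(results, match_truth(results, truth))
        assert report.percent == 100.0

    def test_same_side_bouts_never_overlap(self, week_session):
        for side in Side:
            bouts = [b for b in week_session.bouts if b.side is side]
            for prev, nxt in zip(bouts, bouts[1:]):
                assert nxt.start > prev.end + 1000  # tunnel exclusivity + silence

    def test_true_volume_is_exactly_per_lick_volume(self, week_session):
        for (period, side), ml in week_session.true_volumes_ml.items():
            licks = sum(
                b.size
                for b in week_session.bouts
                if b.period == period and b.side is side
            )
            assert ml == pytest.approx(licks * UL_PER_LICK / 1000.0, rel=1e-12)

    def test_bout_count_within_poisson_interval(self, week_plan, cage_profiles):
        truth = simulate_session(cage_profiles, week_plan, seed=21)
        dark_h = light_h = 12 * 7
        expected = sum(
            p.dark_bout_rate * dark_h + p.light_bout_rate * light_h
            for p in cage_profiles
        )
        lo, hi = poisson.interval(0.99, expected)
        assert lo <= len(truth.bouts) <= hi

    def test_dark_light_lick_ratio_tracks_rate_ratio(self, week_plan):
        prof = lk.MouseProfile(tag="M0", dark_bout_rate=4.0, light_bout_rate=1.0)
        truth = simulate_session([prof], week_plan, seed=31)
        dark = sum(b.size for b in truth.bouts if week_plan.is_dark(b.start))
        light = sum(b.size for b in truth.bouts if not week_plan.is_dark(b.start))
        assert dark / light == pytest.approx(4.0, rel=0.25)


class TestCorruption:
    def test_zero_probabilities_change_nothing(self, week_session):
        assert corrupt_stream(week_session, 0.0, 0.0, seed=3).scans == week_session.scans

    def test_all_scans_missed_leaves_everything_unattributed(self, week_session):
        degraded = corrupt_stream(week_session, missed_scan_p=1.0, seed=3)
        assert degraded.scans == ()
        results = recover_bouts(degraded)
        assert all(r.assigned == lk.UNATTRIBUTED for r in results)
        # ground truth untouched
        assert degraded.bouts == week_session.bouts

    def test_corrupt_one_governing_scan_costs_exactly_one_bout(self, week_session):
        degraded = corrupt_governing_scan(week_session, bout_index=0)
        results = recover_bouts(degraded)
        report = lk.attribution_accuracy(results, match_truth(results, degraded))
        assert report.total == len(week_session.bouts)
        assert report.correct == report.total - 1

    def test_missed_scan_rate_degrades_accuracy(self, week_session):
        degraded = corrupt_stream(week_session, missed_scan_p=0.5, seed=17)
        results = recover_bouts(degraded)
        report = lk.attribution_accuracy(results, match_truth(results, degraded))
        assert report.correct < report.total
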