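"""Synthetic multi-animal two-bottle-choice cage sessions with ground truth.

The simulator emits exactly what the hardware would: per-side lick event
streams and RFID tunnel scans, plus experimenter-style bottle measurements
— together with the ground truth (which mouse produced which bout, true
per-side volumes) that real hardware can never provide.  That makes the
whole processing stack (bout detection, attribution, drinking analysis,
calibration) testable end to end.

Behavioral model, per mouse:

* bout initiations follow an inhomogeneous Poisson process with separate
  dark-phase and light-phase rates (bouts/h), reflecting the strongly
  nocturnal drinking of mice;
* each bout goes to the ethanol bottle with probability ``p`` (the
  configured ethanol preference), mapped to LEFT/RIGHT through the plan's
  current side assignment; in periods without ethanol the side is uniform;
* bout size is log-normal (median ~25 licks); within a bout, lick onsets
  are ~9 Hz (inter-onset ~110 ms) with ~35 ms sipper contacts;
* a correct-tag RFID scan is emitted a fixed lead before the first lick,
  modeling the tunnel pass that precedes drinking.

Only one mouse fits in a tunnel, so same-side bouts of different mice never
overlap; a colliding bout is delayed, not dropped, conserving configured
bout counts.  With ``margin_mode`` (the default) every generated bout is
guaranteed detector-recoverable: the first three onsets span < 900 ms,
internal silences stay < 900 ms, and same-side bouts are separated by more
than 1.1 s plus the scan lead, so detection and attribution recover the
truth exactly on clean streams.

True dispensed volume is exactly 1.4 µl per lick; reported bottle
measurements add Gaussian noise, emulating weighing error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .analysis import UL_PER_LICK
from .attribution import AttributionResult, RFIDScan, attribute_bouts
from .events import Bout, LickEvent, Side, detect_bouts
from .io import (
    BottleMeasurement,
    ExperimentPlan,
    FluidSpec,
    Period,
    iso_to_ms,
)

__all__ = [
    "CageTruth",
    "MouseProfile",
    "SimConfigError",
    "TruthBout",
    "corrupt_governing_scan",
    "corrupt_stream",
    "make_two_bottle_plan",
    "match_truth",
    "recover_bouts",
    "simulate_session",
]

MS_PER_HOUR = 3_600_000

#: Margin-mode timing guarantees (ms): bouts this recoverable can never be
#: split, merged, or mis-scanned by the detector's 1 s rules.
MARGIN_TRIPLE_SPAN_MS = 900
MARGIN_MIN_SILENCE_MS = 1101


class SimConfigError(ValueError):
    """Simulation configuration is infeasible."""


@dataclass(frozen=True)
class MouseProfile:
    """Per-mouse behavioral parameters driving the simulator.

    Rates are bouts per hour; ``ethanol_preference`` is the probability a
    bout targets the ethanol bottle; bout size is log-normal with the given
    median and log-scale sigma; within-bout timing is Gaussian around the
    inter-onset interval and contact duration means (ms); ``scan_lead_ms``
    is how long before the first lick the tunnel reader sees the tag.
    """

    tag: str
    sex: str = "F"
    body_weight_g: float = 25.0
    dark_bout_rate: float = 3.0
    light_bout_rate: float = 0.5
    ethanol_preference: float = 0.5
    bout_size_median: float = 25.0
    bout_size_sigma: float = 0.6
    ioi_mean_ms: float = 110.0
    ioi_sd_ms: float = 15.0
    contact_mean_ms: float = 35.0
    contact_sd_ms: float = 10.0
    scan_lead_ms: int = 500

    def validate(self, margin_mode: bool) -> None:
        if self.dark_bout_rate < 0 or self.light_bout_rate < 0:
            raise SimConfigError(f"{self.tag}: bout rates must be >= 0")
        if not 0 <= self.ethanol_preference <= 1:
            raise SimConfigError(f"{self.tag}: ethanol_preference must lie in [0, 1]")
        if margin_mode and self.ioi_mean_ms >= 1000:
            raise SimConfigError(
                f"{self.tag}: inter-onset mean {self.ioi_mean_ms} ms cannot form "
                "detector-recoverable bouts (three licks must span < 1 s)"
            )
        if self.scan_lead_ms <= 0:
            raise SimConfigError(f"{self.tag}: scan_lead_ms must be > 0")


@dataclass(frozen=True)
class TruthBout:
    """A ground-truth bout: the animal, side, fluid and its member licks."""

    tag: str
    side: Side
    fluid: str
    period: int
    licks: tuple[LickEvent, ...]

    @property
    def start(self) -> int:
        return self.licks[0].onset

    @property
    def end(self) -> int:
        return self.licks[-1].offset

    @property
    def size(self) -> int:
        return len(self.licks)


@dataclass(frozen=True)
class CageTruth:
    """Everything a simulated session emits, plus its ground truth."""

    profiles: tuple[MouseProfile, ...]
    plan: ExperimentPlan
    bouts: tuple[TruthBout, ...]
    scans: tuple[RFIDScan, ...]
    true_volumes_ml: dict  # (period index, Side) -> exact 1.4 µl/lick volume
    measurements: tuple[BottleMeasurement, ...]
    seed: int
    cage: str = "cage0"

    def lick_stream(self, side: Side) -> list[LickEvent]:
        """Merged, time-ordered lick stream for one side (all mice)."""
        licks = [l for b in self.bouts if b.side is side for l in b.licks]
        licks.sort(key=lambda l: l.onset)
        return licks

    def total_licks(self, tag: Optional[str] = None, fluid: Optional[str] = None) -> int:
        return sum(
            b.size
            for b in self.bouts
            if (tag is None or b.tag == tag) and (fluid is None or b.fluid == fluid)
        )


def make_two_bottle_plan(
    start: str,
    stages: Sequence[tuple[int, float]],
    lights_on: str = "07:00",
    lights_off: str = "19:00",
    swap_sides: bool = True,
) -> ExperimentPlan:
    """Build a standard escalating two-bottle-choice plan.

    ``stages`` is a list of ``(days, ethanol_pct)``; a stage with 0 %
    ethanol is a water/water period.  Bottle sides are swapped at each stage
    boundary when ``swap_sides`` (mirroring how bottles are repositioned
    whenever they are weighed, to control side bias).
    """
    t = iso_to_ms(start)
    periods = []
    ethanol_left = False
    for days, pct in stages:
        end = t + days * 24 * MS_PER_HOUR
        if pct > 0:
            etoh = FluidSpec("ethanol", pct)
            water = FluidSpec("water", 0.0)
            left, right = (etoh, water) if ethanol_left else (water, etoh)
        else:
            left = right = FluidSpec("water", 0.0)
        periods.append({"start": t, "end": end, "left": left, "right": right})
        if swap_sides:
            ethanol_left = not ethanol_left
        t = end
    return ExperimentPlan(
        periods=tuple(
            Period(p["start"], p["end"], p["left"], p["right"]) for p in periods
        ),
        lights_on=_clock_minutes(lights_on),
        lights_off=_clock_minutes(lights_off),
    )


def _clock_minutes(text: str) -> int:
    hh, mm = str(text).split(":")
    return int(hh) * 60 + int(mm)


def _light_segments(plan: ExperimentPlan, start: int, end: int):
    """Split [start, end) into maximal constant light/dark segments."""
    boundaries = []
    day_ms = 24 * MS_PER_HOUR
    first_midnight = (start // day_ms) * day_ms
    t = first_midnight
    while t < end + day_ms:
        for minute in (plan.lights_on, plan.lights_off):
            b = t + minute * 60_000
            if start < b < end:
                boundaries.append(b)
        t += day_ms
    edges = [start] + sorted(set(boundaries)) + [end]
    return [(a, b, plan.is_dark(a)) for a, b in zip(edges[:-1], edges[1:])]


def _draw_bout_licks(
    rng: np.random.Generator,
    profile: MouseProfile,
    start: int,
    side: Side,
    margin_mode: bool,
) -> tuple[LickEvent, ...]:
    size = max(3, int(round(np.exp(rng.normal(np.log(profile.bout_size_median), profile.bout_size_sigma)))))
    contacts = np.clip(
        np.round(rng.normal(profile.contact_mean_ms, profile.contact_sd_ms, size)),
        5,
        200,
    ).astype(int)
    onsets = [start]
    for k in range(size - 1):
        lo = contacts[k] + 1  # strictly positive off-contact gap
        hi = contacts[k] + 999  # gap < 1 s keeps the bout unbroken
        if margin_mode:
            hi = min(hi, (MARGIN_TRIPLE_SPAN_MS - 1) // 2)  # triple span < 900 ms
        ioi = int(round(rng.normal(profile.ioi_mean_ms, profile.ioi_sd_ms)))
        ioi = min(max(ioi, lo), max(hi, lo))
        onsets.append(onsets[-1] + ioi)
    return tuple(
        LickEvent(onset=o, contact_duration=int(c), side=side)
        for o, c in zip(onsets, contacts)
    )


def simulate_session(
    profiles: Sequence[MouseProfile],
    plan: ExperimentPlan,
    seed: int,
    *,
    margin_mode: bool = True,
    missed_scan_p: float = 0.0,
    measurement_noise_sd_ml: float = 0.0,
    cage: str = "cage0",
) -> CageTruth:
    """Simulate one cage over the plan's full span.

    Reproducible: identical profiles, plan and seed give identical streams.
    See the module docstring for the behavioral model; ``missed_scan_p``
    independently deletes emitted scans, and bottle measurements are the
    exact 1.4 µl/lick volumes plus Gaussian noise of the given SD (ml).
    """
    if not profiles:
        raise SimConfigError("need at least one mouse profile")
    tags = [p.tag for p in profiles]
    if len(set(tags)) != len(tags):
        raise SimConfigError("mouse tags must be unique")
    for p in profiles:
        p.validate(margin_mode)
    if not 0 <= missed_scan_p <= 1:
        raise SimConfigError("missed_scan_p must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    # 1. bout initiations per mouse: piecewise-constant-rate Poisson process
    proposals = []  # (start, profile, fluid_is_ethanol ~ Bernoulli(p))
    for profile in profiles:
        for period in plan.periods:
            for seg_start, seg_end, dark in _light_segments(plan, period.start, period.end):
                rate = profile.dark_bout_rate if dark else profile.light_bout_rate
                lam = rate * (seg_end - seg_start) / MS_PER_HOUR
                n = rng.poisson(lam)
                starts = np.sort(rng.integers(seg_start, seg_end, size=n))
                wants_ethanol = rng.random(n) < profile.ethanol_preference
                for s, w in zip(starts, wants_ethanol):
                    proposals.append((int(s), profile, bool(w)))
    proposals.sort(key=lambda t: t[0])

    # 2. map each proposal to a side through the plan's current assignment
    skeletons = []  # (start, side, profile)
    for start, profile, wants_ethanol in proposals:
        period = plan.period_at(start)
        if period is None:  # can only happen at exact plan end
            continue
        etoh_sides = [s for s in Side if period.fluid_for(s).ethanol_pct > 0]
        if len(etoh_sides) == 1:
            other = Side.RIGHT if etoh_sides[0] is Side.LEFT else Side.LEFT
            side = etoh_sides[0] if wants_ethanol else other
        else:  # water/water (or ethanol/ethanol): no preference axis, uniform
            side = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
        skeletons.append((start, side, profile))

    # 3. realize lick trains, enforcing per-tunnel exclusivity by delay
    truth_bouts: list[TruthBout] = []
    scans: list[RFIDScan] = []
    for side in Side:
        side_skel = [s for s in skeletons if s[1] is side]
        prev_end: Optional[int] = None
        for start, _side, profile in side_skel:
            if prev_end is not None:
                min_sep = (
                    max(MARGIN_MIN_SILENCE_MS, profile.scan_lead_ms + 1)
                    if margin_mode
                    else 1001
                )
                start = max(start, prev_end + min_sep)
            licks = _draw_bout_licks(rng, profile, start, side, margin_mode)
            period_idx = plan.period_index_at(licks[0].onset)
            if period_idx is None:  # delayed past the plan end: drop
                continue
            fluid = plan.periods[period_idx].fluid_for(side).fluid
            truth_bouts.append(
                TruthBout(
                    tag=profile.tag,
                    side=side,
                    fluid=fluid,
                    period=period_idx,
                    licks=licks,
                )
            )
            scans.append(
                RFIDScan(
                    time=licks[0].onset - profile.scan_lead_ms,
                    tag=profile.tag,
                    reader_side=side,
                )
            )
            prev_end = licks[-1].offset
    truth_bouts.sort(key=lambda b: (b.start, b.side.value))
    scans.sort(key=lambda s: (s.time, s.reader_side.value))
    if missed_scan_p > 0:
        scans = [s for s in scans if rng.random() >= missed_scan_p]

    # 4. true and measured bottle volumes per (period, side)
    true_volumes: dict = {}
    for b in truth_bouts:
        key = (b.period, b.side)
        true_volumes[key] = true_volumes.get(key, 0) + b.size
    true_volumes = {
        k: licks * UL_PER_LICK / 1000.0 for k, licks in true_volumes.items()
    }
    measurements = []
    for idx, period in enumerate(plan.periods):
        for side in Side:
            true_ml = true_volumes.get((idx, side), 0.0)
            noise = rng.normal(0.0, measurement_noise_sd_ml) if measurement_noise_sd_ml > 0 else 0.0
            measurements.append(
                BottleMeasurement(
                    cage=cage,
                    period=idx,
                    side=side,
                    fluid=period.fluid_for(side).fluid,
                    volume_ml=max(0.0, true_ml + noise),
                )
            )

    return CageTruth(
        profiles=tuple(profiles),
        plan=plan,
        bouts=tuple(truth_bouts),
        scans=tuple(scans),
        true_volumes_ml=true_volumes,
        measurements=tuple(measurements),
        seed=seed,
        cage=cage,
    )


def corrupt_stream(
    truth: CageTruth,
    missed_scan_p: float = 0.0,
    wrong_tag_p: float = 0.0,
    seed: int = 0,
) -> CageTruth:
    """Degrade the RFID scan stream; ground truth stays untouched.

    Each scan is independently deleted with ``missed_scan_p`` and, if it
    survives, its tag is swapped to a different mouse's with
    ``wrong_tag_p``.  Returns a copy of ``truth`` with the degraded scans.
    """
    if not 0 <= missed_scan_p <= 1 or not 0 <= wrong_tag_p <= 1:
        raise ValueError("corruption probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tags = [p.tag for p in truth.profiles]
    out = []
    for scan in truth.scans:
        if rng.random() < missed_scan_p:
            continue
        if wrong_tag_p > 0 and rng.random() < wrong_tag_p and len(tags) > 1:
            others = [t for t in tags if t != scan.tag]
            scan = replace(scan, tag=others[rng.integers(len(others))])
        out.append(scan)
    return replace(truth, scans=tuple(out))


def corrupt_governing_scan(
    truth: CageTruth,
    bout_index: int,
    wrong_tag: Optional[str] = None,
) -> CageTruth:
    """Swap the tag of the scan governing one specific truth bout.

    The governing scan is the latest scan on the bout's side at or before
    its start — the one attribution will pick up — so exactly this bout
    becomes misattributed downstream.
    """
    bout = truth.bouts[bout_index]
    candidates = [
        (i, s)
        for i, s in enumerate(truth.scans)
        if s.reader_side is bout.side and s.time <= bout.start
    ]
    if not candidates:
        raise ValueError(f"bout {bout_index} has no governing scan")
    gov_i, gov = max(candidates, key=lambda t: t[1].time)
    if wrong_tag is None:
        others = [p.tag for p in truth.profiles if p.tag != gov.tag]
        if not others:
            raise ValueError("no other tag available to corrupt with")
        wrong_tag = others[0]
    scans = list(truth.scans)
    scans[gov_i] = replace(gov, tag=wrong_tag)
    return replace(truth, scans=tuple(scans))


def recover_bouts(truth: CageTruth, lookback: int = 10_000) -> list[AttributionResult]:
    """Run detection + attribution on the emitted streams, both sides.

    Returns attribution results ordered by bout start — with margin mode on
    and no corruption this reproduces the truth bouts one-for-one.
    """
    results: list[AttributionResult] = []
    for side in Side:
        bouts = detect_bouts(truth.lick_stream(side))
        results.extend(attribute_bouts(bouts, truth.scans, lookback=lookback))
    results.sort(key=lambda r: (r.bout.start, r.bout.side.value))
    return results


def match_truth(results: Sequence[AttributionResult], truth: CageTruth) -> list[str]:
    """True tag per detected bout, matched on (side, start).

    Raises if any detected bout has no ground-truth counterpart (i.e., the
    detector merged or split truth bouts, which margin mode prevents).
    """
    index = {(b.side, b.start): b.tag for b in truth.bouts}
    tags = []
    for r in results:
        key = (r.bout.side, r.bout.start)
        if key not in index:
            raise ValueError(f"detected bout at {key} has no ground-truth match")
        tags.append(index[key])
    return tags
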