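"""Two-bottle-choice drinking analysis on attributed bout logs.

The pipeline mirrors how continuous-access lickometer data are analysed:
bouts are labeled with the fluid behind their sipper (bottle sides are
swapped between recording periods, so the label depends on both side and
time), lick counts are binned into clock-aligned 1 h bins, ethanol
preference is the ethanol share of licks (optionally smoothed with a
centered moving average, window 12 bins by default), consumed volume is
estimated at 1.4 µl per lick, and ethanol intake is expressed in g of
ethanol per kg body weight using an ethanol density of 0.789 g/ml.

Tabular results are tidy :class:`pandas.DataFrame` objects.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .events import Bout, Side, UNASSIGNED, UNATTRIBUTED
from .io import ExperimentPlan, MS_PER_DAY

__all__ = [
    "UL_PER_LICK",
    "ETHANOL_DENSITY_G_PER_ML",
    "DEFAULT_SMOOTHING_WINDOW",
    "UnassignedBoutError",
    "UndefinedPreferenceError",
    "assign_fluids",
    "bin_hourly",
    "bouts_to_frame",
    "daily_summary",
    "average_daily",
    "estimate_volume_ul",
    "ethanol_intake_gkg",
    "moving_average",
    "preference_scalar",
    "preference_series",
]

#: Estimated dispensed volume per lick (µl), from bottle-weight calibration.
UL_PER_LICK = 1.4
#: Density of ethanol at room temperature, g/ml.
ETHANOL_DENSITY_G_PER_ML = 0.789
#: Default moving-average window, in hourly bins.
DEFAULT_SMOOTHING_WINDOW = 12

MS_PER_HOUR = 3_600_000


class UnassignedBoutError(ValueError):
    """Some bouts fall outside every plan period; ``indices`` lists them."""

    def __init__(self, indices: Sequence[int]):
        self.indices = list(indices)
        super().__init__(f"bouts outside all plan periods at indices {self.indices}")


class UndefinedPreferenceError(ValueError):
    """Preference requested with zero licks at both bottles."""


def assign_fluids(bouts: Sequence[Bout], plan: ExperimentPlan) -> list[Bout]:
    """Label each bout with the fluid at its side during its period.

    Membership is decided by the bout start time (bouts last seconds,
    periods days).  Bouts outside every period raise
    :class:`UnassignedBoutError` listing their indices.
    """
    labeled: list[Bout] = []
    outside: list[int] = []
    for i, bout in enumerate(bouts):
        period = plan.period_at(bout.start)
        if period is None:
            outside.append(i)
            continue
        labeled.append(bout.with_fluid(period.fluid_for(bout.side).fluid))
    if outside:
        raise UnassignedBoutError(outside)
    return labeled


def bouts_to_frame(bouts: Iterable[Bout]) -> pd.DataFrame:
    """Flatten bouts into a tidy DataFrame (one row per bout)."""
    rows = [
        {
            "start": b.start,
            "end": b.end,
            "side": b.side.value,
            "animal": b.animal,
            "fluid": b.fluid,
            "size": b.size,
            "bout_duration_ms": b.bout_duration,
            "total_lick_duration_ms": b.total_lick_duration,
            "lick_frequency_hz": b.lick_frequency,
            "est_ili_ms": b.est_ili,
            "flags": "|".join(b.flags),
        }
        for b in bouts
    ]
    columns = [
        "start",
        "end",
        "side",
        "animal",
        "fluid",
        "size",
        "bout_duration_ms",
        "total_lick_duration_ms",
        "lick_frequency_hz",
        "est_ili_ms",
        "flags",
    ]
    return pd.DataFrame(rows, columns=columns)


def _animals_from(bouts: Sequence[Bout], animals: Optional[Sequence[str]]) -> list[str]:
    if animals is not None:
        return list(animals)
    seen: list[str] = []
    for b in bouts:
        if b.animal not in seen:
            seen.append(b.animal)
    return seen


def bin_hourly(
    bouts: Sequence[Bout],
    plan: ExperimentPlan,
    animals: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Bin licks and bouts into clock-aligned 1 h bins per animal and fluid.

    A bout belongs to the half-open bin ``[h, h+1)`` containing its start.
    The output covers the full grid of plan hours x animals x fluids (zeros
    where nothing happened) with columns ``animal, fluid, bin_start,
    lick_count, bout_count, is_dark``.
    """
    for b in bouts:
        if b.fluid == UNASSIGNED:
            raise ValueError("bouts must be fluid-labeled; run assign_fluids first")
    animals = _animals_from(bouts, animals)
    fluids = plan.fluids()
    first_hour = (plan.start // MS_PER_HOUR) * MS_PER_HOUR
    last_hour = ((plan.end - 1) // MS_PER_HOUR) * MS_PER_HOUR
    hours = np.arange(first_hour, last_hour + MS_PER_HOUR, MS_PER_HOUR, dtype=np.int64)
    grid = pd.MultiIndex.from_product(
        [animals, fluids, hours], names=["animal", "fluid", "bin_start"]
    )
    out = pd.DataFrame(index=grid).assign(lick_count=0, bout_count=0)
    if bouts:
        df = bouts_to_frame(bouts)
        df["bin_start"] = (df["start"] // MS_PER_HOUR) * MS_PER_HOUR
        agg = df.groupby(["animal", "fluid", "bin_start"]).agg(
            lick_count=("size", "sum"), bout_count=("size", "count")
        )
        shared = agg.index.intersection(out.index)
        out.loc[shared, ["lick_count", "bout_count"]] = agg.loc[
            shared, ["lick_count", "bout_count"]
        ]
    out = out.reset_index()
    out["is_dark"] = out["bin_start"].map(plan.is_dark)
    out["lick_count"] = out["lick_count"].astype(np.int64)
    out["bout_count"] = out["bout_count"].astype(np.int64)
    return out


def moving_average(values: Sequence[float], window: int) -> np.ndarray:
    """Centered moving mean with shrinking edge windows, skipping NaNs.

    The window at index ``i`` spans ``[i - window//2, i + window - window//2 - 1]``
    (for the default window of 12: six bins back, five forward), truncated
    at the series edges.  Missing values are ignored; a window with no
    finite value yields NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    back = window // 2
    fwd = window - back - 1
    for i in range(len(x)):
        lo = max(0, i - back)
        hi = min(len(x), i + fwd + 1)
        chunk = x[lo:hi]
        finite = chunk[np.isfinite(chunk)]
        if finite.size:
            out[i] = finite.mean()
    return out


def preference_scalar(total_ethanol_licks: float, total_water_licks: float) -> float:
    """Ethanol preference = ethanol licks / (ethanol + water licks)."""
    if total_ethanol_licks < 0 or total_water_licks < 0:
        raise ValueError("lick totals must be >= 0")
    denom = total_ethanol_licks + total_water_licks
    if denom == 0:
        raise UndefinedPreferenceError("preference undefined with zero licks at both bottles")
    return total_ethanol_licks / denom


def preference_series(
    hourly: pd.DataFrame,
    window: int = DEFAULT_SMOOTHING_WINDOW,
    ethanol: str = "ethanol",
    water: str = "water",
) -> pd.DataFrame:
    """Per-animal hourly ethanol preference, raw and smoothed.

    Raw preference per bin is ethanol licks over total licks, missing (NaN)
    where neither bottle was licked; smoothing is the centered moving mean
    of :func:`moving_average` over ``window`` bins, ignoring missing bins.
    Values always lie in [0, 1].
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    pivot = (
        hourly[hourly["fluid"].isin([ethanol, water])]
        .pivot_table(
            index=["animal", "bin_start"],
            columns="fluid",
            values="lick_count",
            aggfunc="sum",
            fill_value=0,
        )
        .reindex(columns=[ethanol, water], fill_value=0)
    )
    frames = []
    for animal, sub in pivot.groupby(level="animal", sort=False):
        e = sub[ethanol].to_numpy(dtype=float)
        w = sub[water].to_numpy(dtype=float)
        total = e + w
        raw = np.where(total > 0, e / np.where(total > 0, total, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "animal": animal,
                    "bin_start": sub.index.get_level_values("bin_start"),
                    "preference_raw": raw,
                    "preference_smoothed": moving_average(raw, window),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["animal", "bin_start", "preference_raw", "preference_smoothed"]
        )
    return pd.concat(frames, ignore_index=True)


def estimate_volume_ul(lick_count: int, ul_per_lick: float = UL_PER_LICK) -> float:
    """Estimated consumed volume (µl): lick count x the per-lick volume.

    The 1.4 µl/lick default comes from bottle-weight calibration and can be
    overridden with a slope-derived value from :mod:`lickometry.calibration`.
    """
    if lick_count < 0:
        raise ValueError("lick_count must be >= 0")
    return ul_per_lick * lick_count


def ethanol_intake_gkg(
    volume_ml: float,
    ethanol_pct_vv: float,
    body_weight_g: float,
    density_g_per_ml: float = ETHANOL_DENSITY_G_PER_ML,
) -> float:
    """Ethanol dose in g per kg body weight.

    ``volume_ml`` of a ``ethanol_pct_vv`` % v/v solution contains
    ``volume x pct/100 x density`` grams of ethanol.
    """
    if volume_ml < 0 or ethanol_pct_vv < 0:
        raise ValueError("volume and concentration must be >= 0")
    if body_weight_g <= 0:
        raise ValueError("body weight must be > 0 g")
    grams = volume_ml * (ethanol_pct_vv / 100.0) * density_g_per_ml
    return grams / (body_weight_g / 1000.0)


def daily_summary(
    bouts: Sequence[Bout],
    plan: ExperimentPlan,
    animals: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Daily microstructure summary per animal, behavioral day, and fluid.

    Days tick over at lights-on so a dark-phase drinking run is never split
    across two days.  Per cell: total licks, bout number, and per-bout means
    of size, bout duration, lick duration (contact per lick), frequency and
    ILI; means are NaN where the cell has no bouts.
    """
    for b in bouts:
        if b.fluid == UNASSIGNED:
            raise ValueError("bouts must be fluid-labeled; run assign_fluids first")
    animals = _animals_from(bouts, animals)
    fluids = plan.fluids()
    first_day = plan.day_index(plan.start)
    last_day = plan.day_index(plan.end - 1)
    days = list(range(first_day, last_day + 1))
    grid = pd.MultiIndex.from_product(
        [animals, days, fluids], names=["animal", "day", "fluid"]
    )
    columns = [
        "total_licks",
        "bout_number",
        "mean_bout_size",
        "mean_bout_duration_ms",
        "mean_lick_duration_ms",
        "mean_lick_frequency_hz",
        "mean_est_ili_ms",
    ]
    out = pd.DataFrame(index=grid, columns=columns, dtype=float)
    out[["total_licks", "bout_number"]] = 0.0
    if bouts:
        df = bouts_to_frame(bouts)
        df["day"] = df["start"].map(plan.day_index)
        df["lick_duration_ms"] = df["total_lick_duration_ms"] / df["size"]
        agg = df.groupby(["animal", "day", "fluid"]).agg(
            total_licks=("size", "sum"),
            bout_number=("size", "count"),
            mean_bout_size=("size", "mean"),
            mean_bout_duration_ms=("bout_duration_ms", "mean"),
            mean_lick_duration_ms=("lick_duration_ms", "mean"),
            mean_lick_frequency_hz=("lick_frequency_hz", "mean"),
            mean_est_ili_ms=("est_ili_ms", "mean"),
        )
        shared = agg.index.intersection(out.index)
        out.loc[shared, columns] = agg.loc[shared, columns]
    out = out.reset_index()
    out["total_licks"] = out["total_licks"].astype(np.int64)
    out["bout_number"] = out["bout_number"].astype(np.int64)
    return out


def average_daily(summary: pd.DataFrame) -> pd.DataFrame:
    """Mean of the daily values per animal and fluid (a recording period's
    "average daily" statistics); days without bouts do not enter the
    per-bout means but do enter the lick/bout totals."""
    metric_cols = [c for c in summary.columns if c.startswith(("total_", "bout_", "mean_"))]
    return (
        summary.groupby(["animal", "fluid"])[metric_cols]
        .mean()
        .reset_index()
    )
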