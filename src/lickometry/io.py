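"""File formats: the per-bout CSV log, experiment plan, and bottle data.

The device logs one row per drinking bout to an SD card.  This package's
bout-log dialect is a plain RFC-4180 CSV with header::

    timestamp_iso,tag_id,side,lick_count,bout_duration_ms,
    total_lick_duration_ms,lick_frequency_hz,est_ili_ms,flags

``timestamp_iso`` is the bout *start* in local ISO-8601 with milliseconds;
frequency and ILI are written with four decimals and re-derived exactly from
the integer columns on read (the written values act as a checksum: rows
whose logged frequency/ILI disagree with the integer metrics by more than
1e-3 relative are rejected with their row number).

The experiment plan is a small YAML document::

    lights_on: "07:00"
    lights_off: "19:00"
    cage_changes: ["2024-01-08 10:00:00"]
    periods:
      - start: 2024-01-01 10:00:00
        end:   2024-01-08 10:00:00
        left:  {fluid: water,   ethanol_pct: 0}
        right: {fluid: ethanol, ethanol_pct: 10}

Bottle measurements are a CSV with columns
``cage,period,side,fluid,volume_ml`` (volume consumed over the period, from
bottle weights).

Lick and RFID scan streams use minimal CSVs (``onset_ms,contact_ms,side``
and ``time_ms,tag,side``) so detection and attribution can be run from
files as well as from memory.
"""

from __future__ import annotations

import csv
import io as _io
import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

import yaml

from .events import (
    Bout,
    LickEvent,
    MIN_BOUT_LICKS,
    Side,
)
from .attribution import RFIDScan

__all__ = [
    "BOUT_LOG_COLUMNS",
    "BottleMeasurement",
    "ExperimentPlan",
    "FluidSpec",
    "ParseError",
    "Period",
    "PlanSchemaError",
    "iso_to_ms",
    "ms_to_iso",
    "read_bout_log",
    "read_licks",
    "read_measurements",
    "read_plan",
    "read_scans",
    "write_bout_log",
    "write_licks",
    "write_measurements",
    "write_scans",
]

BOUT_LOG_COLUMNS = [
    "timestamp_iso",
    "tag_id",
    "side",
    "lick_count",
    "bout_duration_ms",
    "total_lick_duration_ms",
    "lick_frequency_hz",
    "est_ili_ms",
    "flags",
]

_EPOCH = datetime(1970, 1, 1)
MS_PER_DAY = 86_400_000


class ParseError(ValueError):
    """A file failed to parse; ``row`` (1-based, header = 1) locates it."""

    def __init__(self, row: int | None, message: str):
        self.row = row
        where = f"row {row}: " if row is not None else ""
        super().__init__(where + message)


class PlanSchemaError(ValueError):
    """Plan config violates the schema; the message carries the field path."""


def ms_to_iso(ms: int) -> str:
    """Integer ms on the local clock -> ISO-8601 string with milliseconds."""
    dt = _EPOCH + timedelta(milliseconds=int(ms))
    return dt.strftime("%Y-%m-%dT%H:%M:%S.") + f"{dt.microsecond // 1000:03d}"


def iso_to_ms(text: Union[str, datetime]) -> int:
    """ISO-8601 local timestamp (or datetime) -> integer milliseconds."""
    if isinstance(text, datetime):
        dt = text
    else:
        try:
            dt = datetime.fromisoformat(str(text).strip())
        except ValueError as exc:
            raise ParseError(None, f"unparseable timestamp {text!r}") from exc
    delta = dt - _EPOCH
    return round(delta.total_seconds() * 1000)


# ---------------------------------------------------------------------------
# bout log


def _open_for(destination, mode: str):
    if hasattr(destination, "write") or hasattr(destination, "read"):
        return destination, False
    return open(destination, mode, newline=""), True


def write_bout_log(bouts: Sequence[Bout], destination: Union[str, Path, IO[str]]) -> None:
    """Write attributed bouts as the one-row-per-bout CSV log.

    Bouts must be ordered by start time; frequency and ILI columns are
    written with four decimal places.
    """
    for i in range(1, len(bouts)):
        if bouts[i].start < bouts[i - 1].start:
            raise ValueError(f"bouts must be ordered by start (index {i})")
    handle, close = _open_for(destination, "w")
    try:
        writer = csv.writer(handle)
        writer.writerow(BOUT_LOG_COLUMNS)
        for b in bouts:
            writer.writerow(
                [
                    ms_to_iso(b.start),
                    b.animal,
                    b.side.value,
                    b.size,
                    b.bout_duration,
                    b.total_lick_duration,
                    f"{b.lick_frequency:.4f}",
                    f"{b.est_ili:.4f}",
                    "|".join(b.flags),
                ]
            )
    finally:
        if close:
            handle.close()


_METRIC_RTOL = 1e-3


def read_bout_log(source: Union[str, Path, IO[str]]) -> list[Bout]:
    """Read a bout log, re-validating every bout invariant.

    Frequency and ILI are recomputed exactly from the integer columns; rows
    where the logged values disagree beyond 1e-3 relative tolerance, or that
    violate any bout invariant (lick count >= 3, duration consistency), are
    rejected with a :class:`ParseError` naming the row.
    """
    handle, close = _open_for(source, "r")
    try:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(1, "empty file, expected header")
        if header != BOUT_LOG_COLUMNS:
            missing = set(BOUT_LOG_COLUMNS) - set(header)
            raise ParseError(1, f"bad header; missing columns {sorted(missing)}")
        bouts: list[Bout] = []
        for rownum, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(BOUT_LOG_COLUMNS):
                raise ParseError(rownum, f"expected {len(BOUT_LOG_COLUMNS)} fields")
            rec = dict(zip(BOUT_LOG_COLUMNS, row))
            try:
                start = iso_to_ms(rec["timestamp_iso"])
            except ParseError as exc:
                raise ParseError(rownum, str(exc))
            try:
                side = Side(rec["side"])
                size = int(rec["lick_count"])
                duration = int(rec["bout_duration_ms"])
                contact = int(rec["total_lick_duration_ms"])
                freq_logged = float(rec["lick_frequency_hz"])
                ili_logged = float(rec["est_ili_ms"])
            except ValueError as exc:
                raise ParseError(rownum, f"unparseable field: {exc}")
            if size < MIN_BOUT_LICKS:
                raise ParseError(rownum, f"lick_count {size} below bout minimum {MIN_BOUT_LICKS}")
            if duration <= 0 or contact <= 0 or duration < contact:
                raise ParseError(rownum, "durations violate bout invariants")
            freq = size / (duration / 1000.0)
            ili = (duration - contact) / size
            if not math.isclose(freq, freq_logged, rel_tol=_METRIC_RTOL, abs_tol=1e-4):
                raise ParseError(rownum, f"lick_frequency_hz {freq_logged} inconsistent with size/duration ({freq:.4f})")
            if not math.isclose(ili, ili_logged, rel_tol=_METRIC_RTOL, abs_tol=1e-4):
                raise ParseError(rownum, f"est_ili_ms {ili_logged} inconsistent with metrics ({ili:.4f})")
            flags = tuple(f for f in rec["flags"].split("|") if f)
            bouts.append(
                Bout(
                    side=side,
                    start=start,
                    end=start + duration,
                    size=size,
                    bout_duration=duration,
                    total_lick_duration=contact,
                    lick_frequency=freq,
                    est_ili=ili,
                    animal=rec["tag_id"],
                    flags=flags,
                )
            )
        return bouts
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# lick / scan streams


def write_licks(licks: Sequence[LickEvent], destination) -> None:
    handle, close = _open_for(destination, "w")
    try:
        writer = csv.writer(handle)
        writer.writerow(["onset_ms", "contact_ms", "side"])
        for l in licks:
            writer.writerow([l.onset, l.contact_duration, l.side.value])
    finally:
        if close:
            handle.close()


def read_licks(source) -> list[LickEvent]:
    handle, close = _open_for(source, "r")
    try:
        reader = csv.reader(handle)
        header = next(reader, None)
        if header != ["onset_ms", "contact_ms", "side"]:
            raise ParseError(1, "expected header onset_ms,contact_ms,side")
        out = []
        for rownum, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                out.append(LickEvent(int(row[0]), int(row[1]), Side(row[2])))
            except (ValueError, IndexError) as exc:
                raise ParseError(rownum, f"bad lick row: {exc}")
        return out
    finally:
        if close:
            handle.close()


def write_scans(scans: Sequence[RFIDScan], destination) -> None:
    handle, close = _open_for(destination, "w")
    try:
        writer = csv.writer(handle)
        writer.writerow(["time_ms", "tag", "side"])
        for s in scans:
            writer.writerow([s.time, s.tag, s.reader_side.value])
    finally:
        if close:
            handle.close()


def read_scans(source) -> list[RFIDScan]:
    handle, close = _open_for(source, "r")
    try:
        reader = csv.reader(handle)
        header = next(reader, None)
        if header != ["time_ms", "tag", "side"]:
            raise ParseError(1, "expected header time_ms,tag,side")
        out = []
        for rownum, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                out.append(RFIDScan(int(row[0]), row[1], Side(row[2])))
            except (ValueError, IndexError) as exc:
                raise ParseError(rownum, f"bad scan row: {exc}")
        return out
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# experiment plan


@dataclass(frozen=True)
class FluidSpec:
    """Fluid in one bottle: label plus ethanol strength (% v/v, 0 = none)."""

    fluid: str
    ethanol_pct: float = 0.0


@dataclass(frozen=True)
class Period:
    """One recording period with its side -> fluid assignment."""

    start: int
    end: int
    left: FluidSpec
    right: FluidSpec

    def fluid_for(self, side: Side) -> FluidSpec:
        return self.left if side is Side.LEFT else self.right


@dataclass(frozen=True)
class ExperimentPlan:
    """Recording periods, light schedule, and cage-change times.

    ``lights_on`` / ``lights_off`` are minutes past local midnight; the
    cycle must span 12 h + 12 h.  Periods are ordered and non-overlapping.
    """

    periods: tuple[Period, ...]
    lights_on: int
    lights_off: int
    cage_changes: tuple[int, ...] = ()

    @property
    def start(self) -> int:
        return self.periods[0].start

    @property
    def end(self) -> int:
        return self.periods[-1].end

    def period_index_at(self, ms: int) -> int | None:
        """Index of the period containing ``ms`` (half-open), else None."""
        for i, p in enumerate(self.periods):
            if p.start <= ms < p.end:
                return i
        return None

    def period_at(self, ms: int) -> Period | None:
        idx = self.period_index_at(ms)
        return None if idx is None else self.periods[idx]

    def is_dark(self, ms: int) -> bool:
        """True when ``ms`` falls in the lights-off (dark) phase."""
        minute = (ms // 60_000) % 1440
        off, on = self.lights_off, self.lights_on
        if off < on:
            return off <= minute < on
        return minute >= off or minute < on

    def fluids(self) -> list[str]:
        """Distinct fluid labels over all periods, in first-seen order."""
        seen: list[str] = []
        for p in self.periods:
            for spec in (p.left, p.right):
                if spec.fluid not in seen:
                    seen.append(spec.fluid)
        return seen

    def day_start(self, day: int) -> int:
        """Start (ms) of behavioral day ``day``; day 0 opens at the
        lights-on immediately preceding the first period."""
        first = self.periods[0].start
        midnight = (first // MS_PER_DAY) * MS_PER_DAY
        day0 = midnight + self.lights_on * 60_000
        if day0 > first:
            day0 -= MS_PER_DAY
        return day0 + day * MS_PER_DAY

    def day_index(self, ms: int) -> int:
        """Behavioral day of ``ms``: days tick over at lights-on."""
        return (ms - self.day_start(0)) // MS_PER_DAY


def _parse_clock(value, path: str) -> int:
    try:
        text = str(value)
        hh, mm = text.split(":")
        minute = int(hh) * 60 + int(mm)
    except Exception:
        raise PlanSchemaError(f"{path}: expected clock time 'HH:MM', got {value!r}")
    if not 0 <= minute < 1440:
        raise PlanSchemaError(f"{path}: clock time out of range")
    return minute


def _parse_fluid(node, path: str) -> FluidSpec:
    if not isinstance(node, dict) or "fluid" not in node:
        raise PlanSchemaError(f"{path}: expected mapping with 'fluid'")
    pct = node.get("ethanol_pct", 0.0)
    try:
        pct = float(pct)
    except (TypeError, ValueError):
        raise PlanSchemaError(f"{path}.ethanol_pct: expected number, got {pct!r}")
    if not 0 <= pct <= 100:
        raise PlanSchemaError(f"{path}.ethanol_pct: out of [0, 100]")
    return FluidSpec(fluid=str(node["fluid"]), ethanol_pct=pct)


def plan_from_dict(doc: dict) -> ExperimentPlan:
    """Build and validate an :class:`ExperimentPlan` from a parsed mapping."""
    if not isinstance(doc, dict):
        raise PlanSchemaError("plan: expected a mapping at top level")
    for key in ("lights_on", "lights_off", "periods"):
        if key not in doc:
            raise PlanSchemaError(f"{key}: required field missing")
    lights_on = _parse_clock(doc["lights_on"], "lights_on")
    lights_off = _parse_clock(doc["lights_off"], "lights_off")
    if (lights_off - lights_on) % 1440 != 720:
        raise PlanSchemaError("lights_on/lights_off: light cycle must span 12 h + 12 h")
    raw_periods = doc["periods"]
    if not isinstance(raw_periods, list) or not raw_periods:
        raise PlanSchemaError("periods: expected a non-empty list")
    periods: list[Period] = []
    for i, node in enumerate(raw_periods):
        path = f"periods[{i}]"
        if not isinstance(node, dict):
            raise PlanSchemaError(f"{path}: expected a mapping")
        for key in ("start", "end", "left", "right"):
            if key not in node:
                raise PlanSchemaError(f"{path}.{key}: required field missing")
        try:
            start = iso_to_ms(node["start"])
        except ParseError:
            raise PlanSchemaError(f"{path}.start: unparseable timestamp")
        try:
            end = iso_to_ms(node["end"])
        except ParseError:
            raise PlanSchemaError(f"{path}.end: unparseable timestamp")
        if end <= start:
            raise PlanSchemaError(f"{path}: end must be after start")
        periods.append(
            Period(
                start=start,
                end=end,
                left=_parse_fluid(node["left"], f"{path}.left"),
                right=_parse_fluid(node["right"], f"{path}.right"),
            )
        )
    for i in range(1, len(periods)):
        if periods[i].start < periods[i - 1].end:
            raise PlanSchemaError(
                f"periods[{i}]: overlaps or precedes periods[{i - 1}] (periods must be ordered, non-overlapping)"
            )
    changes = []
    for i, node in enumerate(doc.get("cage_changes", []) or []):
        try:
            changes.append(iso_to_ms(node))
        except ParseError:
            raise PlanSchemaError(f"cage_changes[{i}]: unparseable timestamp")
    return ExperimentPlan(
        periods=tuple(periods),
        lights_on=lights_on,
        lights_off=lights_off,
        cage_changes=tuple(changes),
    )


def read_plan(source: Union[str, Path, IO[str]]) -> ExperimentPlan:
    """Read and validate an experiment plan from YAML."""
    handle, close = _open_for(source, "r")
    try:
        doc = yaml.safe_load(handle)
    finally:
        if close:
            handle.close()
    return plan_from_dict(doc)


# ---------------------------------------------------------------------------
# bottle measurements


@dataclass(frozen=True)
class BottleMeasurement:
    """Experimenter-measured volume consumed from one bottle in one period."""

    cage: str
    period: int
    side: Side
    fluid: str
    volume_ml: float

    def __post_init__(self):
        if not math.isfinite(self.volume_ml) or self.volume_ml < 0:
            raise ValueError("volume_ml must be finite and >= 0")


_MEASUREMENT_COLUMNS = ["cage", "period", "side", "fluid", "volume_ml"]


def write_measurements(measurements: Sequence[BottleMeasurement], destination) -> None:
    handle, close = _open_for(destination, "w")
    try:
        writer = csv.writer(handle)
        writer.writerow(_MEASUREMENT_COLUMNS)
        for m in measurements:
            writer.writerow([m.cage, m.period, m.side.value, m.fluid, f"{m.volume_ml:.6f}"])
    finally:
        if close:
            handle.close()


def read_measurements(source) -> list[BottleMeasurement]:
    handle, close = _open_for(source, "r")
    try:
        reader = csv.reader(handle)
        header = next(reader, None)
        if header != _MEASUREMENT_COLUMNS:
            raise ParseError(1, f"expected header {','.join(_MEASUREMENT_COLUMNS)}")
        out = []
        for rownum, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                out.append(
                    BottleMeasurement(
                        cage=row[0],
                        period=int(row[1]),
                        side=Side(row[2]),
                        fluid=row[3],
                        volume_ml=float(row[4]),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(rownum, f"bad measurement row: {exc}")
        return out
    finally:
        if close:
            handle.close()
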