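"""Per-animal attribution of drinking bouts from RFID tunnel scans.

Each sipper sits behind a short tunnel with an RFID reader above it, so the
animal drinking from a side is the one whose tag was read there most
recently.  A bout is assigned the tag of the latest scan on its side at or
before the bout start and within a lookback window (default 10 s); if a
*different* tag is read on that side strictly during the bout, the
assignment is kept but the bout is flagged ``tag-conflict``.  The two sides
are attributed completely independently.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .events import Bout, MalformedStreamError, Side, UNATTRIBUTED

__all__ = [
    "RFIDScan",
    "AttributionResult",
    "AccuracyReport",
    "UndefinedAccuracyError",
    "DEFAULT_LOOKBACK_MS",
    "TAG_CONFLICT",
    "attribute_bouts",
    "attribution_accuracy",
]

DEFAULT_LOOKBACK_MS = 10_000
TAG_CONFLICT = "tag-conflict"


@dataclass(frozen=True, order=True)
class RFIDScan:
    """One tag read at a tunnel reader: time (ms), tag id, reader side."""

    time: int
    tag: str
    reader_side: Side


@dataclass(frozen=True)
class AttributionResult:
    """Outcome of attributing one bout.

    ``bout`` carries the assignment (and any flags); ``latency`` is the ms
    between the governing scan and bout start, ``None`` when unattributed.
    """

    bout: Bout
    assigned: str
    latency: Optional[int]
    tag_conflict: bool = False


class UndefinedAccuracyError(ValueError):
    """Accuracy requested for an empty bout set."""


def _scans_by_side(scans: Sequence[RFIDScan]) -> dict[Side, tuple[list[int], list[str]]]:
    by_side: dict[Side, tuple[list[int], list[str]]] = {
        Side.LEFT: ([], []),
        Side.RIGHT: ([], []),
    }
    last_time: dict[Side, int] = {}
    for i, scan in enumerate(scans):
        prev = last_time.get(scan.reader_side)
        if prev is not None and scan.time < prev:
            raise MalformedStreamError(i, "scans per reader must be ordered by time")
        last_time[scan.reader_side] = scan.time
        times, tags = by_side[scan.reader_side]
        times.append(scan.time)
        tags.append(scan.tag)
    return by_side


def attribute_bouts(
    bouts: Sequence[Bout],
    scans: Sequence[RFIDScan],
    lookback: int = DEFAULT_LOOKBACK_MS,
) -> list[AttributionResult]:
    """Assign each bout to the tag scanned last at its side's tunnel.

    A scan qualifies when it is on the bout's side, its time is <= the bout
    start (equality counts as before), and the bout starts no more than
    ``lookback`` ms after it.  With no qualifying scan the bout stays
    :data:`~lickometry.events.UNATTRIBUTED`.  A different tag scanned on the
    same side strictly inside (start, end) sets the ``tag-conflict`` flag;
    the assignment is never changed or split.
    """
    if lookback <= 0:
        raise ValueError("lookback must be > 0 ms")
    by_side = _scans_by_side(scans)
    results: list[AttributionResult] = []
    for bout in bouts:
        times, tags = by_side[bout.side]
        idx = bisect_right(times, bout.start) - 1
        if idx >= 0 and bout.start - times[idx] <= lookback:
            assigned = tags[idx]
            latency: Optional[int] = bout.start - times[idx]
        else:
            assigned, latency = UNATTRIBUTED, None
        conflict = False
        if assigned != UNATTRIBUTED:
            k = bisect_right(times, bout.start)
            while k < len(times) and times[k] < bout.end:
                if tags[k] != assigned:
                    conflict = True
                    break
                k += 1
        flags = (TAG_CONFLICT,) if conflict else ()
        results.append(
            AttributionResult(
                bout=bout.with_animal(assigned, flags),
                assigned=assigned,
                latency=latency,
                tag_conflict=conflict,
            )
        )
    return results


@dataclass(frozen=True)
class AccuracyReport:
    """Attribution accuracy against ground truth."""

    correct: int
    total: int

    @property
    def percent(self) -> float:
        return 100.0 * self.correct / self.total


def attribution_accuracy(
    results: Sequence[AttributionResult],
    truth: Sequence[str] | Mapping[int, str],
) -> AccuracyReport:
    """Score attribution against the true tag per bout.

    ``truth`` is a tag per bout, aligned with ``results`` (a sequence, or a
    mapping from bout index).  Unattributed bouts count as incorrect.
    Returns the raw counts plus the percentage ``100 * correct / total``.
    """
    if len(results) == 0:
        raise UndefinedAccuracyError("accuracy is undefined for zero bouts")
    if isinstance(truth, Mapping):
        missing = [i for i in range(len(results)) if i not in truth]
        if missing:
            raise ValueError(f"truth missing for bout indices {missing}")
        true_tags = [truth[i] for i in range(len(results))]
    else:
        if len(truth) != len(results):
            raise ValueError(
                f"truth covers {len(truth)} bouts but {len(results)} were attributed"
            )
        true_tags = list(truth)
    correct = sum(
        1
        for res, tag in zip(results, true_tags)
        if res.assigned != UNATTRIBUTED and res.assigned == tag
    )
    return AccuracyReport(correct=correct, total=len(results))
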