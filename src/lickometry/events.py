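"""Drinking-bout detection and per-bout microstructure metrics.

A capacitive lickometer reports each tongue contact ("lick") on a sipper as
an onset timestamp plus a contact duration.  A drinking bout starts when
three licks occur within less than one second and ends when a full second
elapses with no lick; licks that never join a bout (isolated licks, pairs,
unconfirmed triples) are discarded, exactly as the logging firmware behaves.

Per bout, five microstructure metrics are computed:

* ``size`` — number of licks in the bout (bout length),
* ``bout_duration`` — first lick onset to last lick offset, in ms,
* ``total_lick_duration`` — summed sipper contact time, in ms,
* ``lick_frequency`` — ``size / bout_duration`` in Hz,
* ``est_ili`` — estimated inter-lick interval,
  ``(bout_duration - total_lick_duration) / size`` in ms.

All timestamps are integer milliseconds on a single monotonic clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "Side",
    "LickEvent",
    "Bout",
    "BoutMetrics",
    "MalformedStreamError",
    "TooFewLicksError",
    "UNATTRIBUTED",
    "UNASSIGNED",
    "BOUT_START_WINDOW_MS",
    "BOUT_END_SILENCE_MS",
    "MIN_BOUT_LICKS",
    "bout_metrics",
    "detect_bouts",
    "validate_stream",
]

#: Three licks must fall strictly within this many ms to open a bout.
BOUT_START_WINDOW_MS = 1000
#: A silence of at least this many ms (lick offset to next onset) ends a bout.
BOUT_END_SILENCE_MS = 1000
#: Minimum licks per bout.
MIN_BOUT_LICKS = 3

#: Sentinel animal tag for bouts with no qualifying RFID scan.
UNATTRIBUTED = "UNATTRIBUTED"
#: Sentinel fluid label for bouts not yet joined to an experiment plan.
UNASSIGNED = "UNASSIGNED"


class Side(str, Enum):
    """Sipper side of a two-bottle cage."""

    LEFT = "LEFT"
    RIGHT = "RIGHT"

    def __str__(self) -> str:  # writes cleanly into CSV
        return self.value


class MalformedStreamError(ValueError):
    """An event stream violates ordering/overlap invariants.

    ``index`` is the position of the first offending event.
    """

    def __init__(self, index: int, message: str):
        self.index = index
        super().__init__(f"event {index}: {message}")


class TooFewLicksError(ValueError):
    """Fewer licks than the bout minimum were supplied."""


@dataclass(frozen=True, order=True)
class LickEvent:
    """One tongue contact: onset (ms), contact duration (ms), sipper side."""

    onset: int
    contact_duration: int
    side: Side = Side.LEFT

    @property
    def offset(self) -> int:
        """End of sipper contact (ms)."""
        return self.onset + self.contact_duration


class BoutMetrics(NamedTuple):
    """The five logged per-bout microstructure metrics."""

    size: int
    bout_duration: int
    total_lick_duration: int
    lick_frequency: float
    est_ili: float


@dataclass(frozen=True)
class Bout:
    """A detected drinking bout with its logged metrics.

    ``animal`` is an RFID tag once attributed (else :data:`UNATTRIBUTED`);
    ``fluid`` is a plan-derived label (else :data:`UNASSIGNED`); ``flags``
    carries quality markers such as ``"tag-conflict"``.
    """

    side: Side
    start: int
    end: int
    size: int
    bout_duration: int
    total_lick_duration: int
    lick_frequency: float
    est_ili: float
    animal: str = UNATTRIBUTED
    fluid: str = UNASSIGNED
    flags: tuple[str, ...] = ()

    def with_animal(self, tag: str, extra_flags: Iterable[str] = ()) -> "Bout":
        return replace(self, animal=tag, flags=self.flags + tuple(extra_flags))

    def with_fluid(self, fluid: str) -> "Bout":
        return replace(self, fluid=fluid)


def validate_stream(licks: Sequence[LickEvent]) -> None:
    """Check ordering, overlap and side invariants of a one-side stream.

    Raises :class:`MalformedStreamError` naming the first offending event.
    """
    for i, lick in enumerate(licks):
        if lick.contact_duration <= 0:
            raise MalformedStreamError(i, "contact_duration must be > 0")
        if i == 0:
            continue
        prev = licks[i - 1]
        if lick.side is not prev.side:
            raise MalformedStreamError(i, "mixed sides in one stream")
        if lick.onset <= prev.onset:
            raise MalformedStreamError(i, "onsets must be strictly increasing")
        if lick.onset < prev.offset:
            raise MalformedStreamError(i, "contact overlaps previous lick")


def bout_metrics(member_licks: Sequence[LickEvent]) -> BoutMetrics:
    """Compute the logged metrics for the licks of one bout.

    The licks must be ordered and non-overlapping, with at least
    :data:`MIN_BOUT_LICKS` of them.  Frequency is ``size`` over the bout
    duration in seconds; the estimated inter-lick interval is the off-contact
    time per lick, ``(bout_duration - total_lick_duration) / size``.
    """
    if len(member_licks) < MIN_BOUT_LICKS:
        raise TooFewLicksError(
            f"bout needs >= {MIN_BOUT_LICKS} licks, got {len(member_licks)}"
        )
    validate_stream(member_licks)
    size = len(member_licks)
    bout_duration = member_licks[-1].offset - member_licks[0].onset
    total_lick_duration = sum(l.contact_duration for l in member_licks)
    lick_frequency = size / (bout_duration / 1000.0)
    est_ili = (bout_duration - total_lick_duration) / size
    return BoutMetrics(size, bout_duration, total_lick_duration, lick_frequency, est_ili)


def _make_bout(member_licks: Sequence[LickEvent]) -> Bout:
    m = bout_metrics(member_licks)
    first = member_licks[0]
    return Bout(
        side=first.side,
        start=first.onset,
        end=member_licks[-1].offset,
        size=m.size,
        bout_duration=m.bout_duration,
        total_lick_duration=m.total_lick_duration,
        lick_frequency=m.lick_frequency,
        est_ili=m.est_ili,
    )


def detect_bouts(
    licks: Sequence[LickEvent],
    *,
    return_discarded: bool = False,
):
    """Detect drinking bouts in one side's ordered lick stream.

    A bout opens at lick *i* when ``onset(i+2) - onset(i) < 1000`` ms
    (strictly) — the window slides over every candidate anchor — and, once
    open, each further lick joins while the silence from the previous lick's
    offset to its onset stays below 1000 ms.  A silence of >= 1000 ms closes
    the bout.  Licks that never confirm a bout are excluded from the output.

    Parameters
    ----------
    licks:
        Ordered, non-overlapping events, all on one side.
    return_discarded:
        When true, also return the list of licks excluded from every bout.

    Returns
    -------
    list[Bout], or (list[Bout], list[LickEvent]) when ``return_discarded``.
    """
    validate_stream(licks)
    bouts: list[Bout] = []
    discarded: list[LickEvent] = []
    n = len(licks)
    i = 0
    while i < n:
        starts = (
            i + 2 < n
            and licks[i + 2].onset - licks[i].onset < BOUT_START_WINDOW_MS
            and licks[i + 1].onset - licks[i].offset < BOUT_END_SILENCE_MS
            and licks[i + 2].onset - licks[i + 1].offset < BOUT_END_SILENCE_MS
        )
        if not starts:
            discarded.append(licks[i])
            i += 1
            continue
        j = i + 2
        while j + 1 < n and licks[j + 1].onset - licks[j].offset < BOUT_END_SILENCE_MS:
            j += 1
        bouts.append(_make_bout(licks[i : j + 1]))
        i = j + 1
    if return_discarded:
        return bouts, discarded
    return bouts
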