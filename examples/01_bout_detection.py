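"""Detect drinking bouts in a small lick train and print their metrics.

A bout starts when three licks land within less than a second and ends
after a full second of silence; licks that never join a bout are dropped,
exactly as the cage firmware logs them.
"""

from lickometry import LickEvent, Side, detect_bouts

# a fast run of 5 licks, a lone lick 2 s later, then a slow (non-bout) pair
licks = [
    LickEvent(0, 30, Side.LEFT),
    LickEvent(110, 35, Side.LEFT),
    LickEvent(225, 30, Side.LEFT),
    LickEvent(340, 40, Side.LEFT),
    LickEvent(460, 30, Side.LEFT),
    LickEvent(2500, 30, Side.LEFT),
    LickEvent(4000, 30, Side.LEFT),
    LickEvent(4800, 30, Side.LEFT),
]

bouts, discarded = detect_bouts(licks, return_discarded=True)
for b in bouts:
    print(
        f"bout @ {b.start} ms: {b.size} licks, duration {b.bout_duration} ms, "
        f"contact {b.total_lick_duration} ms, "
        f"{b.lick_frequency:.2f} Hz, ILI {b.est_ili:.1f} ms"
    )
print(f"{len(discarded)} licks discarded (never part of a bout)")

# The 5-lick run is one bout (~10 Hz licking); the isolated lick and the
# slow pair never satisfy the three-licks-in-under-a-second start rule.
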