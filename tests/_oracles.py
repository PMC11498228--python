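"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives an expected result by a different route than the
implementation: the bout oracle segments at silences first and then looks
for the earliest qualifying lick triple per segment; the smoothing oracle
loops over explicit window bounds; the regression oracle evaluates the
normal equations in closed form.
"""

from __future__ import annotations

import math

import numpy as np

from lickometry.events import LickEvent


def oracle_bouts(licks: list[LickEvent]) -> list[list[LickEvent]]:
    """Expected bout membership, derived silence-first.

    Split the stream into maximal runs containing no offset-to-onset
    silence of >= 1000 ms; within each run the bout is the suffix starting
    at the earliest lick whose next-next onset lies < 1000 ms after it
    (three licks in under a second); runs without such a triple contribute
    no bout.
    """
    runs: list[list[LickEvent]] = []
    current: list[LickEvent] = []
    for lick in licks:
        if current and lick.onset - current[-1].offset >= 1000:
            runs.append(current)
            current = []
        current.append(lick)
    if current:
        runs.append(current)

    bouts = []
    for run in runs:
        for i in range(len(run) - 2):
            if run[i + 2].onset - run[i].onset < 1000:
                bouts.append(run[i:])
                break
    return bouts


def oracle_moving_average(values, window: int) -> np.ndarray:
    """Centered moving mean with bounds [i - w//2, i + (w - w//2) - 1],
    truncated at the edges, ignoring NaNs."""
    x = np.asarray(values, dtype=float)
    back = window // 2
    fwd = window - back - 1
    out = np.full(len(x), np.nan)
    for i in range(len(x)):
        vals = [
            x[j]
            for j in range(max(0, i - back), min(len(x), i + fwd + 1))
            if math.isfinite(x[j])
        ]
        if vals:
            out[i] = sum(vals) / len(vals)
    return out


def oracle_ols(x, y):
    """Closed-form simple-regression normal equations: slope, intercept, R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - (intercept + slope * x)
    ss_res = (resid**2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    return slope, intercept, 1 - ss_res / ss_tot


def random_lick_train(rng: np.random.Generator, n_events: int) -> list[LickEvent]:
    """A random one-side train with offset-to-onset gaps that straddle the
    1 s boundary: values from {900, 999, 1000, 1001, 1100} ms mixed with
    short within-bout gaps."""
    boundary_gaps = [900, 999, 1000, 1001, 1100]
    licks = []
    t = int(rng.integers(0, 1000))
    for _ in range(n_events):
        contact = int(rng.integers(10, 80))
        licks.append(LickEvent(onset=t, contact_duration=contact))
        if rng.random() < 0.35:
            gap = boundary_gaps[rng.integers(len(boundary_gaps))]
        else:
            gap = int(rng.integers(20, 1300))
        t += contact + gap
    return licks
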