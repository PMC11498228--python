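# Methods

## Bout detection

The detector consumes a time-ordered stream of lick events for one sipper
side; each event is an integer-millisecond onset plus a positive contact
duration, with strictly increasing onsets and no overlapping contacts
(violations raise a malformed-stream error naming the offending event).

Two rules define a bout: it *starts* with three licks in under one second
and *ends* with one second of silence. These leave two details open, fixed
here as follows:

- **Start anchoring.** The start test is a sliding window: a bout opens at
  lick *i* when `onset(i+2) − onset(i) < 1000 ms` (strict). Because the
  off-contact gap between consecutive licks can never exceed their onset
  difference, this window condition already implies that no silence of
  ≥ 1 s occurs inside the triple, making the start rule consistent with the
  end rule for any train.
- **Silence measurement.** Inter-lick silence is measured from the previous
  lick's contact *offset* to the next onset ("no licks" elapses after
  contact ends). The bout terminates at a gap of ≥ 1000 ms, i.e. the
  boundary value counts as termination; once a bout is open, each further
  lick joins while its gap is < 1000 ms, with no re-testing of the triple
  rule inside the bout.

Licks that never confirm a bout — isolated licks, pairs, slow triples, and
licks preceding a confirmed anchor — are excluded from all outputs but can
be returned on request (`return_discarded=True`), so lick counts are
conserved: bout members plus discards equal the input.

Per bout the five logged metrics are size, duration `D` (first onset to
last offset), total contact `C`, frequency `n / D[s]`, and estimated
inter-lick interval `(D − C) / n`. These satisfy `f · D[s] = n` and
`ILI · n + C = D` exactly up to floating rounding; the test suite enforces
both to 1e-9 relative tolerance, and checks boundary equivalence against an
independent oracle that segments at silences first and then looks for the
earliest qualifying triple per segment.

## RFID attribution

A bout is assigned the tag of the most recent scan on its side at or
before its start (equal timestamps qualify), within a lookback window of
10 s by default. The tunnels sit directly over the sippers, so the scan
should immediately precede drinking; the window is configurable because
real dwell behavior is hardware-dependent. A different tag scanned on the
same side strictly inside the bout sets a `tag-conflict` flag; the
assignment is kept and the bout is never split. Sides are fully
independent. Accuracy against ground truth is `100 × correct/total`, with
unattributed bouts counted as incorrect.

## Log and configuration formats

The bout log is an RFC-4180 CSV, one row per bout:
`timestamp_iso,tag_id,side,lick_count,bout_duration_ms,total_lick_duration_ms,lick_frequency_hz,est_ili_ms,flags`.
The timestamp is the bout *start* in local ISO-8601 with milliseconds;
frequency and ILI carry four decimals. On read, both are re-derived from
the integer columns — the written values act as a checksum, and rows that
disagree beyond 1e-3 relative (or violate any bout invariant, e.g. fewer
than three licks) are rejected with their row number. Write-then-read is
therefore bit-exact on valid logs.

The experiment plan is YAML: ordered non-overlapping periods, each with a
side→fluid map (label + ethanol % v/v), clock times for lights-on/off
(validated to a 12 h + 12 h cycle), and optional cage-change timestamps.
Schema errors name the offending field path. Bottle measurements are CSV
(`cage,period,side,fluid,volume_ml`).

## Drinking analysis

- **Fluid labels** come from joining each bout's (side, start) to the
  plan's periods; bin/day membership is decided by bout *start* time, since
  bouts last seconds against hour-scale bins.
- **Hourly binning** uses clock-aligned half-open bins `[h, h+1)` over the
  plan's full span, per animal and fluid, with a dark-phase flag per bin;
  totals conserve bout sizes exactly.
- **Preference** per bin is ethanol licks over total licks, carried as
  missing (not zero) where neither bottle was licked. Smoothing is a
  centered moving average over 12 hourly bins. Convention in the field
  fixes only the window length; this package defines the even-length
  centered window at index *i* to span `[i−6, i+5]`, shrinking at the
  series edges and skipping missing bins. Preference lies in [0, 1] and
  smoothing a constant series is the identity.
- **Volume** is `1.4 µl × licks`; the constant is named and overridable
  with a slope-derived value from the calibration module. **Ethanol
  intake** is `volume_ml × (pct/100) × 0.789 / (weight_g/1000)` g/kg, with
  ethanol density 0.789 g/ml (room temperature). Body weight is an explicit
  argument so callers can supply per-period or whole-experiment means.
- **Daily summaries** aggregate per animal × behavioral day × fluid, with
  day boundaries at *lights-on* rather than midnight so a dark-phase
  drinking run is never split across days. Per-bout means (size, duration,
  lick duration = contact/lick, frequency, ILI) are absent (NaN) on days
  with no bouts; a period's "average daily" value is the mean of its daily
  values.

## Calibration

Total licks per cage-period are regressed on measured bottle-volume change
by ordinary least squares (licks as the response, matching the published
orientation); the slope is licks/ml and `1000/slope`, reported to one
decimal, is the per-lick volume in µl. Confidence intervals are Wald at
95%. Slope equality between two systems is tested as the volume × group
interaction in a pooled linear model — the published comparison names no
test, so the interaction coefficient is this package's choice. Agreement
between lick-derived and weight-derived preference is the same OLS applied
to the paired preference values. Fits are computed by statsmodels and
cross-checked in the tests against closed-form normal equations to 1e-8.

## Cage simulator

The simulator emulates what the hardware records, with full ground truth:

- **Bout initiations** per mouse follow an inhomogeneous Poisson process
  with separate dark/light rates (defaults 3.0 and 0.5 bouts/h — a
  plausibly nocturnal drinker; acceptance scenarios that need ≥ 500 bouts
  per mouse per week use 6.0/0.5).
- **Bottle choice** is Bernoulli with the mouse's ethanol preference `p`,
  mapped to LEFT/RIGHT through the plan's current side assignment; in
  water-only periods the side is uniform.
- **Within-bout timing**: bout sizes are log-normal (median 25 licks,
  σ_log 0.6, floor 3); inter-onset intervals are Gaussian (110 ± 15 ms,
  ≈ 9 Hz licking) and contacts Gaussian (35 ± 10 ms), both clipped to keep
  contacts in [5, 200] ms and every off-contact gap positive and < 1 s.
  True lick-timing distributions for this class of device are not
  published; these are documented synthetic stand-ins, configurable per
  mouse.
- **RFID scans**: one correct-tag scan is emitted a fixed lead (500 ms
  default) before each bout's first lick, modeling the tunnel pass.
- **Tunnel exclusivity**: same-side bouts of different mice never overlap;
  a colliding bout is delayed rather than dropped, conserving configured
  bout counts.
- **Margin mode** (default) makes every generated bout detector-recoverable
  by construction: first-three-onset spans < 900 ms, internal gaps < 900 ms,
  and same-side bouts separated by at least `max(1101 ms, scan_lead + 1)`.
  The separation floor also guarantees that a later bout's scan can never
  precede an earlier bout's start, so clean margin-mode streams yield
  exactly 100% bout recovery and 100% attribution — the property the
  end-to-end tests assert.
- **Volumes**: the true dispensed volume is exactly 1.4 µl × licks;
  reported bottle measurements add Gaussian weighing noise (clamped at
  zero) of configurable SD.
- `corrupt_stream` deletes scans and/or swaps tags independently at given
  probabilities, and `corrupt_governing_scan` mis-tags exactly the scan
  governing one chosen bout — the construction used to reproduce the
  81-of-82 validation arithmetic.

Reproducibility: a session is a pure function of (profiles, plan, seed).

### What the simulator does and does not show

Passing recovery tests on margin-mode streams shows the pipeline is exact
on well-separated bouts; it does not certify behavior on pathological real
streams (bouts abutting within < 1 s across mice, scan dropouts, tag
collisions) — those regimes are exercised separately via non-margin mode
and the corruption operators, where degradation is expected and measured
rather than assumed away. The simulator's preference and microstructure
distributions are qualitative stand-ins, not fits to any cohort; sex and
housing effects are not modeled.

## Statistical checks and problem sizes

The end-to-end check uses a 5-mouse, 7-day cage at dark rate 6 bouts/h
(≈ 2700–2850 bouts), giving each mouse ≥ 500 bouts so its lick-based
preference can be compared against the exact central binomial 99% interval
around its configured `p` with `n` = its bout count. The bottle-choice
process is binomial in *bouts*; the lick-weighted preference is a ratio
estimator with slightly larger dispersion, so the binomial interval is an
approximation for it — the suite also relies on per-bout counts where
exactness matters. Calibration recovery uses 56 simulated cage-period
pairs (14 cages × 2 periods × 2 bottles, drinking rates spanning roughly
an order of magnitude, weighing noise SD 0.05 ml) and asserts the fitted
slope within 2% of 1000/1.4 ≈ 714.3 licks/ml. Detection is validated on
1000 randomized trains whose offset-to-onset gaps deliberately include
900/999/1000/1001/1100 ms to straddle both 1 s boundaries. All suite and
acceptance randomness is seeded.

## Known limitations

- The bout-start/silence conventions above are one consistent reading of
  the stated 1 s rules; firmware measuring silence from lick onset would
  shift boundary cases by one contact duration.
- Attribution implements last-scan-before-start; hardware binding rules
  could differ (e.g. scan-during-bout).
- The bout-log dialect is this package's own (the original SD-card format
  is unpublished); timestamps are naive local time by design, with the
  light schedule carried in the plan.
- Group-level inferential statistics (ANOVAs, multiple-comparison
  corrections, outlier removal) are out of scope; exports are tidy tables
  meant for downstream statistical tools.
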