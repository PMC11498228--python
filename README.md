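# lickometry

Analysis toolkit for home-cage capacitive lickometer experiments in
group-housed mice: drinking-bout detection, RFID-based per-animal
attribution, two-bottle-choice drinking statistics, bottle-weight
calibration, and a full cage simulator with ground truth.

## The problem

Home-cage lickometers record every tongue contact ("lick") a mouse makes on
a bottle sipper, continuously and undisturbed, which makes them the
instrument of choice for studying voluntary ethanol drinking and its
microstructure. In a group-housed cage the device additionally reads a
subcutaneous RFID tag as each mouse passes through a short tunnel to reach
a sipper, so individual intake can be tracked without single housing. The
raw output — per-side lick event streams, tunnel scans, and experimenter
bottle weights — needs a processing stack: turning licks into drinking
bouts, assigning bouts to animals, converting lick counts into volumes and
ethanol doses, and validating the whole chain. This package is that stack,
aimed at behavioral neuroscientists running two-bottle-choice paradigms.

## The model

A **drinking bout** starts when three licks occur in under one second and
ends when a full second passes with no lick (silence measured from the
previous lick's contact offset). Only licks inside a bout are kept. Each
bout is logged with five microstructure metrics:

- bout size `n` (licks) and bout duration `D` (first onset to last offset, ms)
- total lick (contact) duration `C` (ms)
- lick frequency `f = n / D[s]` (Hz)
- estimated inter-lick interval `ILI = (D − C) / n` (ms)

A bout is **attributed** to the tag read most recently at its side's tunnel
(at or before bout start, within a 10 s lookback); a different tag read
during the bout flags a conflict but never splits the bout.

Downstream, licks are binned into clock-aligned 1 h bins; **ethanol
preference** is `ethanol licks / total licks` (smoothed over time with a
centered 12-bin moving average); estimated volume is `1.4 µl × licks`, and
ethanol dose is `volume × (%v/v ÷ 100) × 0.789 g/ml ÷ body weight` in g/kg.
The 1.4 µl constant is the inverse of the calibration slope obtained by
regressing per-period lick totals on measured bottle-volume change
(`licks = slope × ml + b`; `µl/lick = 1000/slope`).

The **simulator** generates whole cages — circadian Poisson bout
initiations per mouse, Bernoulli ethanol-bottle choice, log-normal bout
sizes, ~9 Hz within-bout licking, tunnel scans, noisy bottle weights —
together with the ground truth, so every stage can be validated without
hardware.

## Worked example

Simulate a week of 10% ethanol vs water for five RFID-tagged mice and
recover it with the pipeline (`examples/02_simulated_cage.py`):

```text
ground-truth bouts : 1891
detected bouts     : 1891
attribution        : 1891/1891 = 100.0%
with 20% missed scans: 1518/1891 = 80.3%
```

On clean streams the detector reconstructs every ground-truth bout and the
RFID logic assigns all of them to the right mouse; deleting 20% of scans
shows how missed reads degrade attribution. The analysis layer
(`examples/03_preference_analysis.py`) then recovers each mouse's
configured ethanol preference and converts licks to intake:

```text
M0: true p=0.3  measured preference=0.274  ethanol 3.4 ml over the week  (10.8 g/kg total)
M1: true p=0.6  measured preference=0.623  ethanol 7.6 ml over the week  (23.9 g/kg total)
M2: true p=0.9  measured preference=0.920  ethanol 11.3 ml over the week  (35.5 g/kg total)

dark-phase share of licking: 87% (mice are nocturnal drinkers)
```

`examples/01_bout_detection.py` and `examples/04_calibration.py` walk the
bout rules and the lick-volume regression. A thin CLI mirrors the same
stages for file-based use:

```bash
lickometry simulate  --config sim.yaml --seed 3 --out session/
lickometry detect    --licks session/licks_left.csv --out bouts.csv
lickometry attribute --bouts bouts.csv --scans session/scans.csv --out attributed.csv
lickometry summarize --log attributed.csv --plan plan.yaml --out tables/
lickometry calibrate --log attributed.csv --measurements session/bottles.csv --plan plan.yaml
```

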