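"""Calibrate lick counts against bottle weights.

Regresses total licks per cage-period on the experimenter-measured volume
change; the slope (licks/ml) inverts to the per-lick volume in µl, the
constant the analysis uses to convert lick counts to consumed volume.
"""

import numpy as np

import lickometry as lk
from lickometry.calibration import compare_slopes, fit_lick_volume, volume_per_lick

rng = np.random.default_rng(5)

# synthetic cage-period bottle data: mice take ~1.4 µl per lick, the scale
# reads volumes with ~0.05 ml error
licks = rng.integers(1_000, 9_000, 56)
volumes_ml = licks * 1.4e-3 + rng.normal(0, 0.05, 56)

fit = fit_lick_volume(volumes_ml, licks)
print(f"slope     : {fit.slope:.1f} licks/ml "
      f"(95% CI {fit.slope_ci[0]:.1f}-{fit.slope_ci[1]:.1f})")
print(f"intercept : {fit.intercept:.1f} licks")
print(f"R-squared : {fit.r_squared:.4f}")
print(f"per lick  : {volume_per_lick(fit)} ul")

# Are two devices' calibrations interchangeable? Test slope equality with a
# pooled interaction model.
licks_b = rng.integers(1_000, 9_000, 56)
volumes_b = licks_b * 1.4e-3 + rng.normal(0, 0.05, 56)
cmp = compare_slopes(volumes_ml, licks, volumes_b, licks_b)
print(f"\nslope difference vs second device: {cmp.slope_difference:.1f} licks/ml "
      f"(p = {cmp.pvalue:.2f}) -> "
      f"{'no evidence the devices differ' if cmp.pvalue > 0.05 else 'devices differ'}")
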