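"""Lickometer-to-bottle-weight calibration.

Lickometry is validated against experimenter-weighed bottles by regressing
the total lick count recorded per cage-period on the measured volume change
(ordinary least squares, licks = slope x ml + intercept).  The slope is the
number of licks per ml; its reciprocal, 1000/slope, is the dispensed volume
per lick in µl — the constant used to convert lick counts to volume.  The
module also tests whether two systems' calibration slopes differ (pooled
model with a group x volume interaction) and quantifies agreement between
preference computed from licks and from bottle weights.

Fits are delegated to :mod:`statsmodels`; confidence intervals are Wald.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionFit",
    "SlopeComparison",
    "compare_slopes",
    "fit_lick_volume",
    "preference_agreement",
    "volume_per_lick",
]


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary-least-squares fit of licks on volume (or any y on x)."""

    slope: float
    intercept: float
    r_squared: float
    slope_ci: tuple[float, float]
    n: int
    residual_se: float

    def __post_init__(self):
        lo, hi = self.slope_ci
        if not lo <= self.slope <= hi:
            raise ValueError("slope must lie inside its confidence interval")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class SlopeComparison:
    """Test of slope equality between two fitted calibration lines."""

    slope_difference: float
    ci: tuple[float, float]
    statistic: float
    pvalue: float


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        n=int(model.nobs),
        residual_se=float(np.sqrt(model.mse_resid)),
    )


def _validate_pairs(x, y, name_x: str, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expected two equal-length 1-d vectors")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError(f"{name_x} has zero variance; slope is unidentifiable")
    return x, y


def fit_lick_volume(volumes_ml: Sequence[float], licks: Sequence[float]) -> RegressionFit:
    """OLS of total licks on measured volume change per cage-period.

    The slope is in licks per ml.  Requires >= 3 pairs with non-degenerate
    volumes; volumes must be >= 0.
    """
    x, y = _validate_pairs(volumes_ml, licks, "volumes")
    if (x < 0).any():
        raise ValueError("volumes must be >= 0 ml")
    return _ols(x, y)


def volume_per_lick(fit_or_slope: RegressionFit | float) -> float:
    """Dispensed volume per lick (µl), 1000/slope, to one decimal place."""
    slope = fit_or_slope.slope if isinstance(fit_or_slope, RegressionFit) else float(fit_or_slope)
    if slope <= 0:
        raise ValueError("slope must be > 0 licks/ml")
    return round(1000.0 / slope, 1)


def compare_slopes(
    volumes_a: Sequence[float],
    licks_a: Sequence[float],
    volumes_b: Sequence[float],
    licks_b: Sequence[float],
) -> SlopeComparison:
    """Test slope equality of two lick-volume calibrations.

    Fits the pooled model ``licks ~ volume + group + volume:group`` and
    reports the interaction coefficient (the slope difference B - A) with
    its Wald CI, t statistic, and p value.
    """
    xa, ya = _validate_pairs(volumes_a, licks_a, "volumes_a")
    xb, yb = _validate_pairs(volumes_b, licks_b, "volumes_b")
    x = np.concatenate([xa, xb])
    g = np.concatenate([np.zeros(len(xa)), np.ones(len(xb))])
    y = np.concatenate([ya, yb])
    design = sm.add_constant(np.column_stack([x, g, x * g]))
    model = sm.OLS(y, design).fit()
    ci = model.conf_int(alpha=0.05)
    return SlopeComparison(
        slope_difference=float(model.params[3]),
        ci=(float(ci[3, 0]), float(ci[3, 1])),
        statistic=float(model.tvalues[3]),
        pvalue=float(model.pvalues[3]),
    )


def preference_agreement(
    pref_by_licks: Sequence[float],
    pref_by_volume: Sequence[float],
) -> RegressionFit:
    """Agreement between lick-derived and weight-derived preference.

    OLS of the lick-based preference on the volume-based preference per
    cage-period; both inputs must lie in [0, 1].  R-squared near 1 means the
    lick counts reproduce the bottle-weight preference.
    """
    x, y = _validate_pairs(pref_by_volume, pref_by_licks, "pref_by_volume")
    if ((x < 0) | (x > 1)).any() or ((y < 0) | (y > 1)).any():
        raise ValueError("preference values must lie in [0, 1]")
    return _ols(x, y)
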