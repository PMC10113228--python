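"""Emergence timing and synchronization metrics.

Per species, daily predicted activity (full-model response-scale
predictions summed over hours and sites per day of year) defines a weight
distribution over days.  Its weighted median is the timing of emergence;
the interquartile range (IQR) — the number of days holding the middle 50%
of activity — measures synchronization: the smaller, the more synchronized
the species leaves its hibernacula.  Cross-species ordinary least squares
regressions relate residual activity, timing and synchronization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .errors import DataError
from .gapm import FittedGAPM, predict
from .residuals import ResidualActivityCurve


@dataclass
class EmergenceSummary:
    """Activity-weighted timing and spread of one species' spring activity."""

    species: str
    median_doy: float
    q1: float
    q3: float
    iqr: float
    mean_doy: float
    mean_residual: float        # mean of signed residual-activity values
    mean_abs_residual: float

    def __post_init__(self):
        if not (self.q1 <= self.median_doy <= self.q3):
            raise ValueError("quantiles out of order")


def daily_predicted_activity(fit: FittedGAPM, frame: pd.DataFrame) -> pd.Series:
    """Full-model response-scale predictions summed per day of year."""
    mu = predict(fit, frame, scale="response")
    return pd.Series(mu).groupby(frame["DOY"].to_numpy()).sum().sort_index()


def weighted_quantiles(days, weights, q):
    """Weighted quantile(s) of a discrete day distribution.

    Linear interpolation on the cumulative normalized weights with the
    midpoint convention (mass of day d is centred at cumulative position
    F(d-) + w_d/2), so symmetric weights return the centre of symmetry.
    """
    days = np.asarray(days, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise DataError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise DataError("weights must have positive sum")
    order = np.argsort(days, kind="stable")
    days, w = days[order], w[order]
    cum = (np.cumsum(w) - 0.5 * w) / total
    return np.interp(q, cum, days)


def emergence_summary(
    daily: pd.Series, curve: ResidualActivityCurve
) -> EmergenceSummary:
    """Median/quartile timing from the daily activity distribution."""
    days = daily.index.to_numpy(float)
    w = daily.to_numpy(float)
    q1, med, q3 = weighted_quantiles(days, w, [0.25, 0.5, 0.75])
    mean_doy = float(np.sum(days * w) / np.sum(w))
    return EmergenceSummary(
        species=curve.species,
        median_doy=float(med), q1=float(q1), q3=float(q3),
        iqr=float(q3 - q1), mean_doy=mean_doy,
        mean_residual=float(np.mean(curve.value)),
        mean_abs_residual=float(np.mean(np.abs(curve.value))),
    )


def cross_species_regression(summaries: list[EmergenceSummary]) -> pd.DataFrame:
    """OLS fits of (median DOY ~ mean residual) and (IQR ~ median DOY).

    Returns one row per regression with slope, intercept, R^2 and the
    two-sided p-value of the slope.
    """
    if len(summaries) < 3:
        raise DataError("cross-species regression needs at least 3 species")
    tab = pd.DataFrame([s.__dict__ for s in summaries])
    rows = []
    for yvar, xvar in (("median_doy", "mean_residual"), ("iqr", "median_doy")):
        res = linregress(tab[xvar], tab[yvar])
        rows.append((f"{yvar} ~ {xvar}", res.slope, res.intercept,
                     res.rvalue ** 2, res.pvalue))
    return pd.DataFrame(rows, columns=["model", "slope", "intercept",
                                       "r_squared", "p"]).set_index("model")
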