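"""Sunrise/sunset from standard solar geometry.

Implements the NOAA low-precision solar position equations (Fourier series
in the fractional year for declination and the equation of time, zenith
90.833 deg for refraction-corrected rise/set).  Accuracy is on the order of
one to two minutes at temperate latitudes, which is ample for constructing
the sun-time covariate: activity is aggregated hourly, so minute-level
errors in the anchors are negligible.

All timestamps are UTC (the synthetic study world uses a single clock).
"""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pandas as pd

from .config import SiteConfig

_ZENITH_DEG = 90.833


class PolarDayError(ValueError):
    """Sun does not rise or set on this date at this latitude."""


def _fractional_year(date: dt.date, hour: float = 12.0) -> float:
    doy = date.timetuple().tm_yday
    return 2.0 * math.pi / 365.0 * (doy - 1 + (hour - 12.0) / 24.0)

def _eqtime_min(g: float) -> float:
    return 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )

def _declination_rad(g: float) -> float:
    return (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )


def solar_events(site: SiteConfig, date: dt.date) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Sunrise and sunset (UTC) for ``site`` on ``date``.

    Raises :class:`PolarDayError` during polar day/night, which is outside
    the supported domain (the study sites are temperate).
    """
    if isinstance(date, (pd.Timestamp, dt.datetime)):
        date = pd.Timestamp(date).date()
    g = _fractional_year(date)
    decl = _declination_rad(g)
    lat = math.radians(site.latitude)
    cos_ha = (
        math.cos(math.radians(_ZENITH_DEG)) / (math.cos(lat) * math.cos(decl))
        - math.tan(lat) * math.tan(decl)
    )
    if not -1.0 < cos_ha < 1.0:
        raise PolarDayError(
            f"no sunrise/sunset at latitude {site.latitude} on {date}"
        )
    ha_deg = math.degrees(math.acos(cos_ha))
    eqtime = _eqtime_min(g)
    sunrise_min = 720.0 - 4.0 * (site.longitude + ha_deg) - eqtime
    sunset_min = 720.0 - 4.0 * (site.longitude - ha_deg) - eqtime
    base = pd.Timestamp(date)
    sunrise = base + pd.to_timedelta(sunrise_min, unit="m")
    sunset = base + pd.to_timedelta(sunset_min, unit="m")
    return sunrise.round("s"), sunset.round("s")


def solar_table(site: SiteConfig, dates) -> pd.DataFrame:
    """Sunrise/sunset per date as a DataFrame indexed by date."""
    rows = []
    for d in dates:
        d = pd.Timestamp(d).date()
        sr, ss = solar_events(site, d)
        rows.append((pd.Timestamp(d), sr, ss))
    return pd.DataFrame(rows, columns=["date", "sunrise", "sunset"]).set_index("date")
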