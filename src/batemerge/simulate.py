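"""Species-specific activity simulation from the generative model.

``simulate_activity`` produces an event stream (individual barrier
crossings with second-resolution timestamps): for each site-hour the total
movement count is Poisson with log-mean given by the model equation, split
binomially into entries and exits, and scattered uniformly within the hour.

``simulate_model_frame`` skips the event layer and draws the hourly
response directly from the same equation — the appropriate generator for
parameter-recovery and calibration studies, where the min-of-smoothed-
aggregates response construction would add a deliberate downward bias.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import SiteConfig, TrueModel, WEATHER_COVARIATES
from .errors import DataError
from .preprocess import DAY_MAX_DEFAULT, covariate_frame
from .weather import WeatherParams, simulate_weather

log = logging.getLogger(__name__)

EVENT_COLUMNS = ["timestamp", "site_id", "species", "direction"]


def _eta(truth: TrueModel, cov: pd.DataFrame) -> np.ndarray:
    covs = {c: cov[c].to_numpy(float) for c in WEATHER_COVARIATES}
    site = cov["site_id"].to_numpy()
    g = np.array([truth.site_effects.get(s, 0.0) for s in site])
    g += truth.alpha
    for name in WEATHER_COVARIATES:
        b = truth.beta.get(name, 0.0)
        if b:
            g += b * covs[name]
    g += truth.f1_truth(cov["ST"].to_numpy(float))
    g += truth.f2_truth(cov["DOY"].to_numpy(float))
    if truth.f3_truth is not None:
        g += truth.f3_truth(cov["ST"].to_numpy(float), cov["DOY"].to_numpy(float))
    return g


def simulate_activity(
    truth: TrueModel,
    weather: pd.DataFrame,
    sites: list[SiteConfig],
    seed: int,
    species: str = "species",
    day_max: int = DAY_MAX_DEFAULT,
) -> pd.DataFrame:
    """Event records drawn from the generative model; deterministic per seed.

    Hours with a missing covariate are skipped (counted in the log): no
    movements can be simulated without a complete linear predictor.
    """
    cov = covariate_frame(weather, sites, day_max=day_max)
    cols = list(WEATHER_COVARIATES) + ["ST", "DOY"]
    ok = ~cov[cols].isna().any(axis=1)
    if (~ok).any():
        log.warning("skipping %d site-hours with missing weather", int((~ok).sum()))
    cov = cov[ok].sort_values(["site_id", "timestamp"]).reset_index(drop=True)

    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 101])
    mu = np.exp(np.clip(_eta(truth, cov), -30.0, 30.0))
    total = rng.poisson(mu)
    n_in = rng.binomial(total, truth.split_fraction)
    n_out = total - n_in

    hours = pd.to_datetime(cov["timestamp"]).to_numpy()
    site = cov["site_id"].to_numpy()
    recs = []
    for direction, counts in (("in", n_in), ("out", n_out)):
        nz = np.nonzero(counts)[0]
        for i in nz:
            offs = np.sort(rng.integers(0, 3600, size=counts[i]))
            for o in offs:
                recs.append((hours[i] + np.timedelta64(int(o), "s"),
                             site[i], species, direction))
    ev = pd.DataFrame(recs, columns=EVENT_COLUMNS)
    return ev.sort_values(["timestamp", "site_id", "direction"],
                          kind="stable").reset_index(drop=True)


def simulate_model_frame(
    truth: TrueModel,
    n: int,
    seed: int,
    sites: list[SiteConfig] | None = None,
    start_year: int = 2015,
    day_max: int = DAY_MAX_DEFAULT,
    weather_params: WeatherParams | None = None,
) -> pd.DataFrame:
    """A model frame of ``n`` site-hours with y ~ Poisson(exp(g)).

    Weather is simulated year by year (January 1 to ``day_max``) over the
    configured sites until ``n`` complete rows accumulate, mirroring the
    multi-year coverage of a real monitoring scheme.
    """
    from .config import default_sites

    sites = sites if sites is not None else default_sites()
    cols = list(WEATHER_COVARIATES) + ["ST", "DOY"]
    pieces, total = [], 0
    year = start_year
    while total < n:
        wx = simulate_weather(sites, f"{year}-01-01", day_max + 2,
                              seed=(int(seed) + 7919 * (year - start_year)) & 0x7FFFFFFF,
                              params=weather_params)
        cov = covariate_frame(wx, sites, day_max=day_max)
        cov = cov[~cov[cols].isna().any(axis=1)]
        cov = cov.sort_values(["site_id", "timestamp"]).reset_index(drop=True)
        pieces.append(cov)
        total += len(cov)
        year += 1
        if year - start_year > 50:
            raise DataError("cannot accumulate requested n site-hours")
    frame = pd.concat(pieces, ignore_index=True).head(n).copy()
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 211])
    mu = np.exp(np.clip(_eta(truth, frame), -30.0, 30.0))
    frame["y"] = rng.poisson(mu).astype(float)
    frame["DOY"] = frame["DOY"].astype(int)
    frame = frame.rename(columns={"timestamp": "hour"})
    return frame


def inject_gaps(
    events: pd.DataFrame,
    gap_spec: list[tuple],
    weather: pd.DataFrame,
    missing_spec: list[tuple] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove events in per-site windows and blank weather fields.

    ``gap_spec``: (site_id, start, end) windows of recorder outage —
    overlapping windows for a site are merged with a warning.
    ``missing_spec``: (site_id, field, start, end) windows where a weather
    field was not observed.  Removal counts are logged.
    """
    ev = events.copy()
    wx = weather.copy()

    by_site: dict[str, list[list[pd.Timestamp]]] = {}
    for site, start, end in gap_spec:
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        if end < start:
            raise DataError(f"gap window for {site!r} has end before start")
        by_site.setdefault(site, []).append([start, end])
    merged_spec = []
    for site, wins in by_site.items():
        wins.sort()
        merged = [wins[0]]
        for s, e in wins[1:]:
            if s <= merged[-1][1]:
                log.warning("overlapping gap windows for %s merged", site)
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        merged_spec += [(site, s, e) for s, e in merged]

    removed = 0
    if len(ev):
        ts = pd.to_datetime(ev["timestamp"])
        drop = pd.Series(False, index=ev.index)
        for site, s, e in merged_spec:
            drop |= (ev["site_id"] == site) & (ts >= s) & (ts < e)
        removed = int(drop.sum())
        ev = ev[~drop].reset_index(drop=True)
    log.info("inject_gaps removed %d event records", removed)

    blanked = 0
    for site, field, s, e in (missing_spec or []):
        if field not in wx.columns:
            raise DataError(f"unknown weather field {field!r}")
        ts = pd.to_datetime(wx["timestamp"])
        m = (wx["site_id"] == site) & (ts >= pd.Timestamp(s)) & (ts < pd.Timestamp(e))
        blanked += int(m.sum())
        wx.loc[m, field] = np.nan
    log.info("inject_gaps blanked %d weather values", blanked)
    return ev, wx
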