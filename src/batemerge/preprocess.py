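"""From raw entry/exit events and hourly weather to the model frame.

Processing steps, in order:

1. events are aggregated to hourly in/out counts per site and species,
   with explicit zero rows for covered hours without events;
2. both hourly count series are smoothed by a 3-hour moving average
   (robustness against short-term disturbances such as a predator);
3. the response is the *minimum* of the two smoothed series, which damps
   one-way bulk movements during the final emergence;
4. weather covariates are joined by site-hour; the air-pressure trend
   APT_t = AP_{t+1} - AP_{t-1} and the sun time ST are added;
5. rows after day-of-year ``day_max`` (default 136, mid-May) and rows with
   any missing covariate are dropped, with per-reason accounting.

Day-of-year convention: January 1 = day 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import WEATHER_COVARIATES, SiteConfig
from .errors import DataError
from .solar import solar_table

log = logging.getLogger(__name__)

DAY_MAX_DEFAULT = 136


def aggregate_hourly(events: pd.DataFrame, span: dict | None = None) -> pd.DataFrame:
    """Hourly in/out counts per site and species.

    ``span`` optionally maps site_id -> (start, end) timestamps defining the
    covered recording period (e.g. from the weather table); by default the
    span is the site's first to last event hour.  Hours without events are
    present with zero counts.  Records with an invalid direction are
    rejected and counted in the log.
    """
    cols = ["site_id", "species", "hour", "n_in", "n_out"]
    if len(events) == 0:
        return pd.DataFrame(columns=cols)
    ev = events.copy()
    ev["timestamp"] = pd.to_datetime(ev["timestamp"])
    good = ev["direction"].isin(["in", "out"])
    if (~good).any():
        log.warning("rejected %d event records with invalid direction",
                    int((~good).sum()))
        ev = ev[good]
    ev["hour"] = ev["timestamp"].dt.floor("h")
    counts = (
        ev.groupby(["site_id", "species", "hour", "direction"], observed=True)
        .size().unstack("direction", fill_value=0)
        .reindex(columns=["in", "out"], fill_value=0)
        .rename(columns={"in": "n_in", "out": "n_out"})
        .reset_index()
    )
    out = []
    for site, site_counts in counts.groupby("site_id", observed=True):
        if span is not None and site in span:
            start, end = (pd.Timestamp(t).floor("h") for t in span[site])
        else:
            start, end = site_counts["hour"].min(), site_counts["hour"].max()
        hours = pd.date_range(start, end, freq="h")
        for sp, sub in site_counts.groupby("species", observed=True):
            full = sub.set_index("hour").reindex(hours)
            full["site_id"] = site
            full["species"] = sp
            full[["n_in", "n_out"]] = full[["n_in", "n_out"]].fillna(0).astype(int)
            full = full.rename_axis("hour").reset_index()
            out.append(full[cols])
    return pd.concat(out, ignore_index=True)


def smooth_counts(series) -> np.ndarray:
    """Centred 3-hour moving average with shrunken windows at the edges."""
    x = np.asarray(series, dtype=float)
    if len(x) == 0:
        return x
    kern = np.ones(3)
    num = np.convolve(x, kern, mode="same")
    den = np.convolve(np.ones_like(x), kern, mode="same")
    return num / den


def build_response(s_in, s_out):
    """Response = the smaller of the two smoothed aggregates."""
    return np.minimum(s_in, s_out)


def compute_apt(ap) -> np.ndarray:
    """Air-pressure trend APT_t = AP_{t+1} - AP_{t-1}; endpoints missing."""
    ap = np.asarray(ap, dtype=float)
    apt = np.full_like(ap, np.nan)
    if len(ap) >= 3:
        apt[1:-1] = ap[2:] - ap[:-2]
    return apt


def compute_sun_time(timestamps, events: pd.DataFrame) -> np.ndarray:
    """Sun time ST in [-1, 1] from surrounding sunrise/sunset anchors.

    ``events`` is a table with ``sunrise`` and ``sunset`` columns covering
    the dates of ``timestamps`` (at least one day of slack either side).
    Sunset maps to 0; the night interpolates linearly to +1 at the next
    sunrise; the day interpolates from -1 at sunrise to 0 at sunset, so ST
    is continuous and periodic with period 2 at the sunrise seam.
    Timestamps outside the covered anchor range yield NaN.
    """
    ts = pd.DatetimeIndex(pd.to_datetime(timestamps)).asi8.astype(float)
    rises = pd.DatetimeIndex(events["sunrise"]).asi8.astype(float)
    sets = pd.DatetimeIndex(events["sunset"]).asi8.astype(float)
    times = np.concatenate([rises, sets])
    is_rise = np.concatenate([np.ones(len(rises), bool), np.zeros(len(sets), bool)])
    order = np.argsort(times, kind="stable")
    times, is_rise = times[order], is_rise[order]
    idx = np.searchsorted(times, ts, side="right") - 1
    st = np.full(len(ts), np.nan)
    ok = (idx >= 0) & (idx + 1 < len(times))
    i = idx[ok]
    frac = (ts[ok] - times[i]) / (times[i + 1] - times[i])
    st[ok] = np.where(is_rise[i], -1.0 + frac, frac)
    return st


def covariate_frame(
    weather: pd.DataFrame,
    sites: list[SiteConfig],
    day_max: int = DAY_MAX_DEFAULT,
) -> pd.DataFrame:
    """Per site-hour covariate table: weather + APT + ST + DOY.

    APT is computed per site assuming hourly-contiguous weather; ST uses the
    site's coordinates.  Rows keep NaNs (filtering happens downstream).
    """
    site_map = {s.site_id: s for s in sites}
    pieces = []
    for site_id, wx in weather.groupby("site_id", observed=True):
        if site_id not in site_map:
            raise DataError(f"no coordinates configured for site {site_id!r}")
        wx = wx.sort_values("timestamp").reset_index(drop=True)
        wx["APT"] = compute_apt(wx["AP"].to_numpy())
        ts = pd.to_datetime(wx["timestamp"])
        dates = pd.date_range(ts.min().normalize() - pd.Timedelta(days=1),
                              ts.max().normalize() + pd.Timedelta(days=1))
        anchors = solar_table(site_map[site_id], dates)
        wx["ST"] = compute_sun_time(ts, anchors)
        wx["DOY"] = ts.dt.dayofyear.to_numpy() - 1
        pieces.append(wx)
    out = pd.concat(pieces, ignore_index=True)
    return out[out["DOY"] <= day_max].reset_index(drop=True)


def assemble_model_frame(
    hourly: pd.DataFrame,
    weather: pd.DataFrame,
    sites: list[SiteConfig],
    day_max: int = DAY_MAX_DEFAULT,
) -> pd.DataFrame:
    """Join smoothed hourly activity with covariates into the model frame.

    The 3-hour moving average is applied per contiguous block of recorded
    hours so that data gaps do not bleed across.  Rows with day of year
    beyond ``day_max`` or any missing covariate are dropped; the counts per
    reason are logged and stored in ``frame.attrs['drops']``.
    """
    missing_sites = set(hourly["site_id"].unique()) - set(weather["site_id"].unique())
    if missing_sites:
        raise DataError(f"activity sites missing from weather: {sorted(missing_sites)}")

    smoothed = []
    for (site, sp), sub in hourly.groupby(["site_id", "species"], observed=True):
        sub = sub.sort_values("hour").reset_index(drop=True)
        gap = sub["hour"].diff() > pd.Timedelta(hours=1)
        block = gap.cumsum()
        s_in = np.concatenate([
            smooth_counts(b["n_in"].to_numpy()) for _, b in sub.groupby(block)
        ])
        s_out = np.concatenate([
            smooth_counts(b["n_out"].to_numpy()) for _, b in sub.groupby(block)
        ])
        sub["s_in"], sub["s_out"] = s_in, s_out
        sub["y"] = build_response(s_in, s_out)
        smoothed.append(sub)
    activity = pd.concat(smoothed, ignore_index=True)

    cov = covariate_frame(weather, sites, day_max=day_max)
    cov = cov.rename(columns={"timestamp": "hour"})
    cov["hour"] = pd.to_datetime(cov["hour"])
    activity["hour"] = pd.to_datetime(activity["hour"])

    n0 = len(activity)
    doy_act = activity["hour"].dt.dayofyear - 1
    keep = doy_act <= day_max
    dropped_doy = int((~keep).sum())
    activity = activity[keep]

    merged = activity.merge(cov, on=["site_id", "hour"], how="left")
    covariate_cols = list(WEATHER_COVARIATES) + ["ST", "DOY"]
    bad = merged[covariate_cols].isna().any(axis=1)
    dropped_missing = int(bad.sum())
    frame = merged[~bad].reset_index(drop=True)
    frame["DOY"] = frame["DOY"].astype(int)

    drops = {"doy_beyond_max": dropped_doy, "missing_covariate": dropped_missing,
             "input_rows": n0, "output_rows": len(frame)}
    log.info("model frame: %s", drops)
    frame.attrs["drops"] = drops
    cols = ["site_id", "species", "hour", "n_in", "n_out", "s_in", "s_out",
            "y"] + covariate_cols
    return frame[cols]
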