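"""Synthetic hourly weather with the correlation structure the analysis assumes.

The generator does not try to match real climatology; it reproduces the
*structure* that matters for the downstream model: a seasonal and diel air
temperature cycle with persistent noise, a soil temperature that is a
heavily lagged low-variance smoothing of air temperature (soil thermal
inertia at 20 cm depth), a slowly drifting air pressure around 1013 hPa,
non-negative wind, zero-inflated precipitation with wet-spell persistence,
and integer cloud cover (eighths) correlated with wet hours.  Default
parameters keep all pairwise covariate correlations below ~0.5, matching
the low-collinearity regime the study design relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SiteConfig

WEATHER_COLUMNS = ["site_id", "timestamp", "T_S", "T_A", "AP", "WS", "PR", "CC"]


@dataclass
class WeatherParams:
    """Tunable generator parameters (units in comments)."""

    t_mean: float = 8.0          # annual mean air temperature, degC
    t_season_amp: float = 9.0    # seasonal half-amplitude, degC
    t_season_phase: float = 15.0 # coldest day of year (DOY, Jan 1 = 0)
    t_diel_amp: float = 4.0      # diel half-amplitude, degC
    t_noise_sd: float = 3.5      # stationary s.d. of AR(1) air-temp noise, degC
    t_noise_phi: float = 0.95    # hourly AR(1) coefficient
    soil_tau_h: float = 2400.0   # soil low-pass time constant, hours (100 days)
    soil_noise_sd: float = 0.05  # soil measurement noise, degC
    soil_slow_sd: float = 2.5    # independent slow soil component, degC
    soil_slow_phi: float = 0.999 # AR(1) coefficient of the slow component
    ap_mean: float = 1013.0      # hPa
    ap_sd: float = 8.0           # stationary s.d. of pressure, hPa
    ap_phi: float = 0.99         # hourly AR(1) coefficient (synoptic, ~4 d)
    ws_mean: float = 3.0         # m/s, location of the latent wind process
    ws_sd: float = 1.8           # m/s, scale of the latent wind process
    ws_phi: float = 0.9
    p_wet_given_dry: float = 0.04
    p_wet_given_wet: float = 0.70
    pr_mean_mm: float = 1.2      # mean hourly rain amount when wet
    cc_phi: float = 0.85
    cc_wet_shift: float = 2.5    # extra cloud eighths during wet hours


def _ar1(rng: np.random.Generator, n: int, phi: float, stat_sd: float) -> np.ndarray:
    e_sd = stat_sd * np.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = rng.normal(0.0, stat_sd)
    eps = rng.normal(0.0, e_sd, size=n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


def simulate_weather(
    sites: list[SiteConfig],
    start_date,
    n_days: int,
    seed: int,
    params: WeatherParams | None = None,
) -> pd.DataFrame:
    """One row per site per hour, deterministic given ``seed``.

    ``n_days`` must be at least 2 because the pressure-trend covariate
    (APT) needs both temporal neighbours of an hour.
    """
    if n_days < 2:
        raise ValueError("n_days must be >= 2 (APT needs neighbouring hours)")
    params = params or WeatherParams()
    start = pd.Timestamp(start_date)
    n = n_days * 24
    hours = start + pd.to_timedelta(np.arange(n), unit="h")
    doy = hours.dayofyear.to_numpy() - 1  # Jan 1 = 0
    hod = hours.hour.to_numpy()

    frames = []
    for idx, site in enumerate(sorted(sites, key=lambda s: s.site_id)):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, idx])
        seasonal = params.t_mean - params.t_season_amp * np.cos(
            2.0 * np.pi * (doy - params.t_season_phase) / 365.25
        )
        diel = -params.t_diel_amp * np.cos(2.0 * np.pi * (hod - 14.0) / 24.0)
        t_det = seasonal + diel
        t_a = t_det + _ar1(rng, n, params.t_noise_phi, params.t_noise_sd)

        # soil: first-order low-pass of air temperature (thermal inertia)
        t_s = np.empty(n)
        t_s[0] = seasonal[0]
        k = 1.0 / params.soil_tau_h
        for t in range(1, n):
            t_s[t] = t_s[t - 1] + k * (t_a[t] - t_s[t - 1])
        t_s += _ar1(rng, n, params.soil_slow_phi, params.soil_slow_sd)
        t_s += rng.normal(0.0, params.soil_noise_sd, size=n)

        ap = params.ap_mean + _ar1(rng, n, params.ap_phi, params.ap_sd)

        ws_lat = params.ws_mean + params.ws_sd * _ar1(rng, n, params.ws_phi, 1.0)
        ws = np.log1p(np.exp(ws_lat))  # softplus: smooth, strictly positive

        wet = np.zeros(n, dtype=bool)
        u = rng.random(n)
        wet[0] = u[0] < 0.1
        for t in range(1, n):
            p = params.p_wet_given_wet if wet[t - 1] else params.p_wet_given_dry
            wet[t] = u[t] < p
        pr = np.where(wet, rng.exponential(params.pr_mean_mm, size=n), 0.0)

        cc_lat = 4.0 + 2.0 * _ar1(rng, n, params.cc_phi, 1.0) \
            + params.cc_wet_shift * wet
        cc = np.clip(np.rint(cc_lat), 0, 8).astype(int)

        frames.append(pd.DataFrame({
            "site_id": site.site_id,
            "timestamp": hours,
            "T_S": t_s,
            "T_A": t_a,
            "AP": ap,
            "WS": ws,
            "PR": pr,
            "CC": cc,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out[WEATHER_COLUMNS]
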