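"""End-to-end pipeline: simulate -> preprocess -> fit -> residuals -> emergence.

``run_pipeline`` executes the whole analysis for a :class:`PipelineConfig`
and writes all artifacts (CSV tables, model bundles, reports and a run log
with row-drop accounting) into the output directory.  Every random draw is
seeded, so two runs with the same configuration produce byte-identical CSV
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .config import (
    SPECIES_SITES,
    ConfigError,
    SiteConfig,
    default_sites,
    species_list,
    species_truth,
)
from .emergence import (
    cross_species_regression,
    daily_predicted_activity,
    emergence_summary,
)
from .gapm import (
    ModelSpec,
    SmoothSpec,
    TensorSpec,
    deviance_explained,
    fit_gapm,
    smooth_significance,
    wald_tests,
)
from .preprocess import DAY_MAX_DEFAULT, aggregate_hourly, assemble_model_frame
from .residuals import classify_groups, median_abs_residual, residual_activity
from .simulate import inject_gaps, simulate_activity
from .weather import simulate_weather

log = logging.getLogger(__name__)

MIN_ROWS_PER_SPECIES = 100


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML."""

    outdir: str = "results/run"
    events_path: str | None = None     # None -> simulate
    weather_path: str | None = None
    sites: list[SiteConfig] = field(default_factory=default_sites)
    species: list[str] = field(default_factory=species_list)
    day_max: int = DAY_MAX_DEFAULT
    seed: int = 20230101
    n_days: int = DAY_MAX_DEFAULT + 2
    start_date: str = "2016-01-01"
    gap_spec: list = field(default_factory=list)
    missing_spec: list = field(default_factory=list)
    alpha: float = 0.05
    min_rows: int = MIN_ROWS_PER_SPECIES
    model: ModelSpec = field(default_factory=ModelSpec)

    def __post_init__(self):
        if not 2 <= self.day_max <= 366:
            raise ConfigError("day_max must be in [2, 366]")


def config_from_yaml(path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    sites = [SiteConfig(**s) for s in doc.pop("sites", [])] or default_sites()
    model_doc = doc.pop("model", {})
    spec_kwargs = {}
    for key in ("f1", "f2"):
        if key in model_doc:
            v = model_doc.pop(key)
            spec_kwargs[key] = None if v is None else SmoothSpec(
                v["n_basis"], tuple(v["period"]))
    if "f3" in model_doc:
        v = model_doc.pop("f3")
        spec_kwargs["f3"] = None if v is None else TensorSpec(**v)
    spec_kwargs.update(model_doc)
    unknown = set(doc) - set(PipelineConfig.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(sites=sites, model=ModelSpec(**spec_kwargs), **doc)


def demo_config(outdir: str = "results/demo") -> PipelineConfig:
    """A small, fast, fully simulated demonstration run (2 species, 3 sites)."""
    sites = [s for s in default_sites()
             if s.site_id in ("Mayen-Mauerstollen", "Kaub-Rennleiterstollen",
                              "Neukirchen-Sulzbach")]
    return PipelineConfig(
        outdir=outdir,
        sites=sites,
        species=["M_myotis", "M_bechsteinii", "P_auritus_austriacus"],
        seed=20230101,
        model=ModelSpec(
            f1=SmoothSpec(8, (-1.0, 1.0)),
            f2=SmoothSpec(12, (0.0, 366.0)),
            f3=None,
            lambda_grid=tuple(np.logspace(-3.0, 5.0, 5)),
            sweeps=1,
        ),
    )


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("batemerge").addHandler(handler)
    return handler


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the artifact directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    try:
        return _run(config, outdir)
    finally:
        logging.getLogger("batemerge").removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> Path:
    site_ids = {s.site_id for s in config.sites}

    # ---- data: read or simulate -------------------------------------
    if config.weather_path:
        weather = bio.read_weather(config.weather_path)
    else:
        weather = simulate_weather(config.sites, config.start_date,
                                   config.n_days, seed=config.seed)
    if config.events_path:
        events = bio.read_events(config.events_path)
    else:
        pieces = []
        for k, sp in enumerate(sorted(config.species)):
            hosts = [s for s in config.sites
                     if s.site_id in SPECIES_SITES.get(sp, site_ids)]
            if not hosts:
                log.warning("species %s occurs at none of the sites", sp)
                continue
            wx = weather[weather.site_id.isin([s.site_id for s in hosts])]
            pieces.append(simulate_activity(
                species_truth(sp), wx, hosts, seed=config.seed + 13 * k + 1,
                species=sp, day_max=config.day_max))
        events = pd.concat(pieces, ignore_index=True).sort_values(
            ["timestamp", "site_id", "species", "direction"],
            kind="stable").reset_index(drop=True)
    if config.gap_spec or config.missing_spec:
        events, weather = inject_gaps(events, config.gap_spec, weather,
                                      config.missing_spec)
    bio.write_events(events, outdir / "events.csv")
    bio.write_weather(weather, outdir / "weather.csv")

    # ---- preprocess --------------------------------------------------
    span = {sid: (g.timestamp.min(), g.timestamp.max())
            for sid, g in weather.groupby("site_id")}
    hourly = aggregate_hourly(events, span=span)
    frame = assemble_model_frame(hourly, weather, config.sites,
                                 day_max=config.day_max)
    bio.write_model_frame(frame, outdir / "model_frame.csv")
    log.info("row accounting: %s", frame.attrs.get("drops"))

    # ---- fit per species ---------------------------------------------
    fits, table_rows = {}, []
    for sp in sorted(frame["species"].unique()):
        sub = frame[frame.species == sp].reset_index(drop=True)
        if len(sub) < config.min_rows:
            log.warning("species %s skipped: only %d rows (< %d)",
                        sp, len(sub), config.min_rows)
            continue
        fit = fit_gapm(sub, config.model, species=sp)
        fits[sp] = (fit, sub)
        bio.save_model(fit, outdir / f"model_{sp}.json")
        wt = wald_tests(fit).reset_index()
        wt.insert(0, "species", sp)
        sig = smooth_significance(fit).reset_index()
        sig.insert(0, "species", sp)
        table_rows.append((sp, wt, sig, deviance_explained(fit), fit.n_obs))

    if table_rows:
        pd.concat([t[1] for t in table_rows]).to_csv(
            outdir / "table_coefficients.csv", index=False, float_format="%.6f")
        pd.concat([t[2] for t in table_rows]).to_csv(
            outdir / "table_smooths.csv", index=False, float_format="%.6f")
        pd.DataFrame(
            [(sp, de, n) for sp, _, _, de, n in table_rows],
            columns=["species", "deviance_explained", "n_obs"],
        ).to_csv(outdir / "table_model_summary.csv", index=False,
                 float_format="%.6f")

    # ---- residual activity and groups ---------------------------------
    curves = {}
    for sp, (fit, _sub) in fits.items():
        curve = residual_activity(fit)
        curves[sp] = curve
        curve.to_frame().to_csv(outdir / f"residual_curve_{sp}.csv",
                                index=False, float_format="%.6f")
    if len(curves) >= 2:
        groups = classify_groups(list(curves.values()), alpha=config.alpha)
        rep = pd.DataFrame({
            "species": groups.ranking,
            "median_abs_residual": [groups.medians[s] for s in groups.ranking],
            "letters": [groups.letters[s] for s in groups.ranking],
            "label": [groups.labels[s] for s in groups.ranking],
        })
        rep.to_csv(outdir / "group_report.csv", index=False,
                   float_format="%.6f")
        groups.p_matrix.to_csv(outdir / "group_p_matrix.csv",
                               float_format="%.6f")

    # ---- emergence timing ---------------------------------------------
    summaries = []
    for sp, (fit, sub) in fits.items():
        daily = daily_predicted_activity(fit, sub)
        summaries.append(emergence_summary(daily, curves[sp]))
    if summaries:
        pd.DataFrame([s.__dict__ for s in summaries]).to_csv(
            outdir / "emergence_summary.csv", index=False,
            float_format="%.6f")
    if len(summaries) >= 3:
        cross_species_regression(summaries).reset_index().to_csv(
            outdir / "cross_species_regressions.csv", index=False,
            float_format="%.6f")
    log.info("pipeline complete: %s", outdir)
    return outdir
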