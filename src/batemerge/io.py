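"""CSV readers/writers and model persistence.

Formats (all plain text):

* events CSV — columns ``timestamp`` (ISO-8601), ``site_id``, ``species``,
  ``direction`` (``in``/``out``);
* weather CSV — one row per site-hour, columns ``site_id, timestamp, T_S,
  T_A, AP, WS, PR, CC`` (the "package" dialect); a "dwd-like" dialect maps
  observation-network column names and normalizes the -999 missing sentinel;
* model frame CSV — the assembled per-site-hour rows with response and
  covariates;
* model bundle — a single versioned JSON file holding the fitted
  coefficients, covariance, smoothing parameters, knots and constraint
  transforms, sufficient to reload a fit for prediction.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from .errors import DataError
from .gapm import FittedGAPM, ModelSpec, SmoothSpec, TensorSpec
from .simulate import EVENT_COLUMNS
from .splines import CyclicBasis, TensorBasis
from .weather import WEATHER_COLUMNS

log = logging.getLogger(__name__)

BUNDLE_VERSION = "batemerge-gapm-1"

_DWD_COLUMNS = {
    "STATIONS_ID": "site_id",
    "MESS_DATUM": "timestamp",
    "V_TE020": "T_S",
    "TT_TU": "T_A",
    "P": "AP",
    "F": "WS",
    "R1": "PR",
    "V_N": "CC",
}


def read_events(path) -> pd.DataFrame:
    """Read an event CSV; malformed rows are rejected with counted warnings."""
    df = pd.read_csv(path, dtype=str)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"events file lacks columns: {sorted(missing)}")
    n0 = len(df)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    ok = ts.notna() & df["direction"].isin(["in", "out"]) \
        & df["site_id"].notna() & df["species"].notna()
    if (~ok).any():
        log.warning("rejected %d malformed event rows", int((~ok).sum()))
    out = df[ok].copy()
    out["timestamp"] = ts[ok]
    out = out.reset_index(drop=True)
    log.info("read %d/%d event records", len(out), n0)
    return out[EVENT_COLUMNS]


def write_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S")
    out[EVENT_COLUMNS].to_csv(path, index=False)


def read_weather(path, dialect: str = "package") -> pd.DataFrame:
    """Read a weather CSV in the given dialect.

    ``package``: native column names.  ``dwd-like``: observation-network
    style names with -999 as the missing-value sentinel.
    """
    if dialect == "package":
        df = pd.read_csv(path)
    elif dialect == "dwd-like":
        df = pd.read_csv(path).rename(columns=_DWD_COLUMNS)
        num_cols = [c for c in WEATHER_COLUMNS if c not in ("site_id", "timestamp")]
        for c in num_cols:
            if c in df.columns:
                df[c] = pd.to_numeric(df[c], errors="coerce")
                df.loc[df[c] <= -999.0, c] = np.nan
    else:
        raise DataError(
            f"unknown weather dialect {dialect!r}; supported: package, dwd-like"
        )
    missing = set(WEATHER_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"weather file lacks columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["site_id"] = df["site_id"].astype(str)
    return df[WEATHER_COLUMNS]


def write_weather(weather: pd.DataFrame, path) -> None:
    out = weather.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format="%.6f")


def write_model_frame(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    out["hour"] = pd.to_datetime(out["hour"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format="%.6f")


def read_model_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["hour"] = pd.to_datetime(df["hour"])
    df["site_id"] = df["site_id"].astype(str)
    return df


def _spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "covariates": list(spec.covariates),
        "site_reference": spec.site_reference,
        "f1": None if spec.f1 is None else
            {"n_basis": spec.f1.n_basis, "period": list(spec.f1.period)},
        "f2": None if spec.f2 is None else
            {"n_basis": spec.f2.n_basis, "period": list(spec.f2.period)},
        "f3": None if spec.f3 is None else
            {"n_basis_st": spec.f3.n_basis_st, "n_basis_doy": spec.f3.n_basis_doy},
        "method": spec.method,
        "knot_placement": spec.knot_placement,
    }


def _spec_from_dict(d: dict) -> ModelSpec:
    return ModelSpec(
        covariates=tuple(d["covariates"]),
        site_reference=d["site_reference"],
        f1=None if d["f1"] is None else
            SmoothSpec(d["f1"]["n_basis"], tuple(d["f1"]["period"])),
        f2=None if d["f2"] is None else
            SmoothSpec(d["f2"]["n_basis"], tuple(d["f2"]["period"])),
        f3=None if d["f3"] is None else
            TensorSpec(d["f3"]["n_basis_st"], d["f3"]["n_basis_doy"]),
        method=d["method"],
        fixed_lambdas={},
        knot_placement=d["knot_placement"],
    )


def save_model(fit: FittedGAPM, path) -> None:
    """Persist a fitted model as a versioned JSON bundle."""
    bases = {}
    for name, val in fit.bases.items():
        if name == "f3":
            tensor: TensorBasis = val
            bases[name] = {
                "knots_st": tensor.margin_x.knots.tolist(),
                "knots_doy": tensor.margin_y.knots.tolist(),
                "C_st": tensor.C_x.tolist(),
                "C_doy": tensor.C_y.tolist(),
            }
        else:
            basis, C = val
            bases[name] = {"knots": basis.knots.tolist(), "C": C.tolist()}
    doc = {
        "version": BUNDLE_VERSION,
        "species": fit.species,
        "bases": bases,
        "spec": _spec_to_dict(fit.spec),
        "coef": fit.coef.tolist(),
        "cov": fit.cov.tolist(),
        "col_names": fit.col_names,
        "blocks": {k: [v.start, v.stop] for k, v in fit.blocks.items()},
        "lambdas": {k: float(v) for k, v in fit.lambdas.items()},
        "deviance": fit.deviance,
        "null_deviance": fit.null_deviance,
        "edf_total": fit.edf_total,
        "edf_by_block": fit.edf_by_block,
        "n_obs": fit.n_obs,
        "site_levels": fit.site_levels,
        "reference": fit.reference,
        "ranges": {k: list(v) for k, v in fit.ranges.items()},
        "n_iter": fit.n_iter,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> FittedGAPM:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("version") != BUNDLE_VERSION:
        raise DataError(
            f"unsupported model bundle version {doc.get('version')!r}"
        )
    return _fit_from_doc(doc, _spec_from_dict(doc["spec"]))


def _fit_from_doc(doc: dict, spec: ModelSpec) -> FittedGAPM:
    bases = {}
    for name, b in doc["bases"].items():
        if name == "f3":
            bx = CyclicBasis.from_knots(np.asarray(b["knots_st"]))
            by = CyclicBasis.from_knots(np.asarray(b["knots_doy"]))
            Cx = np.asarray(b["C_st"])
            Cy = np.asarray(b["C_doy"])
            Sx = Cx.T @ bx.penalty @ Cx
            Sy = Cy.T @ by.penalty @ Cy
            bases[name] = TensorBasis(
                bx, by, Cx, Cy,
                np.kron(Sx, np.eye(Cy.shape[1])),
                np.kron(np.eye(Cx.shape[1]), Sy),
            )
        else:
            basis = CyclicBasis.from_knots(np.asarray(b["knots"]))
            bases[name] = (basis, np.asarray(b["C"]))
    return FittedGAPM(
        spec=spec,
        coef=np.asarray(doc["coef"]),
        cov=np.asarray(doc["cov"]),
        col_names=list(doc["col_names"]),
        blocks={k: slice(a, b) for k, (a, b) in doc["blocks"].items()},
        lambdas=doc["lambdas"],
        deviance=doc["deviance"],
        null_deviance=doc["null_deviance"],
        edf_total=doc["edf_total"],
        edf_by_block=doc["edf_by_block"],
        n_obs=doc["n_obs"],
        site_levels=doc["site_levels"],
        reference=doc["reference"],
        bases=bases,
        ranges={k: tuple(v) for k, v in doc["ranges"].items()},
        n_iter=doc["n_iter"],
        species=doc["species"],
    )
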