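"""Penalized Poisson generalized additive model (log link).

The model for the hourly movement count y at observation k is

    y_k ~ Poisson(mu_k),   log(mu_k) = alpha + site_k + x_k' beta
                           + f1(ST_k) + f2(DOY_k) + f3(ST_k, DOY_k)

with f1, f2 cyclic cubic regression splines (periods 2 and one year) and f3
a main-effects-excluded tensor-product interaction.  Fitting is by
penalized iteratively reweighted least squares (IRLS); smoothing parameters
are chosen by minimizing the GCV score n*D / (n - edf)^2 over a log-spaced
grid with coordinate descent.

The response is allowed to be non-integer and non-negative: the observed
response is the minimum of two 3-hour moving averages, so the Poisson
log-likelihood is read as a quasi-likelihood, with deviance

    D = 2 * sum[ y*log(y/mu) - (y - mu) ],   y*log(y) := 0 at y = 0,

which is well defined for real y >= 0.  The dispersion is fixed at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import xlogy
from scipy.stats import chi2, norm

from .config import DEFAULT_REFERENCE_SITE, WEATHER_COVARIATES, ConfigError
from .errors import NumericError, DataError
from .splines import (
    CyclicBasis,
    TensorBasis,
    apply_sum_to_zero,
    build_cyclic_basis,
    build_tensor_basis,
)

log = logging.getLogger(__name__)

_ETA_CLIP = 30.0


@dataclass(frozen=True)
class SmoothSpec:
    """Basis dimension and period of one cyclic smooth term."""

    n_basis: int
    period: tuple[float, float]


@dataclass(frozen=True)
class TensorSpec:
    """Marginal dimensions of the ST x DOY interaction smooth."""

    n_basis_st: int = 5
    n_basis_doy: int = 5


@dataclass(frozen=True)
class ModelSpec:
    """Right-hand side of the GAPM and fitting options."""

    covariates: tuple[str, ...] = WEATHER_COVARIATES
    site_reference: str = DEFAULT_REFERENCE_SITE
    f1: SmoothSpec | None = SmoothSpec(10, (-1.0, 1.0))
    f2: SmoothSpec | None = SmoothSpec(20, (0.0, 366.0))
    f3: TensorSpec | None = TensorSpec(5, 5)
    method: str = "GCV"               # "GCV" or "fixed"
    fixed_lambdas: dict | None = None  # absolute lambdas for method="fixed"
    lambda_grid: tuple[float, ...] = tuple(np.logspace(-5.0, 5.0, 11))
    sweeps: int = 2
    knot_placement: str = "quantile"
    tol: float = 1e-8
    maxiter: int = 100

    def __post_init__(self):
        if not self.covariates:
            raise ConfigError("covariate list must be non-empty")
        if self.method not in ("GCV", "fixed"):
            raise ConfigError(f"unknown smoothing method {self.method!r}")


@dataclass
class Design:
    """Assembled design matrix with block structure and penalty blocks."""

    X: np.ndarray
    col_names: list[str]
    blocks: dict               # name -> slice into columns
    penalties: list            # (lambda-name, slice, penalty matrix on block)
    site_levels: list[str]
    reference: str | None
    linear_means: np.ndarray   # centering offsets of the linear covariates
    bases: dict                # "f1"/"f2" -> (CyclicBasis, C), "f3" -> TensorBasis
    ranges: dict               # covariate name -> (min, max) seen in training


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Real-valued Poisson deviance, valid for non-integer y >= 0."""
    return float(2.0 * np.sum(xlogy(y, y) - xlogy(y, mu) - (y - mu)))


def build_design(frame: pd.DataFrame, spec: ModelSpec) -> Design:
    n = len(frame)
    if n == 0:
        raise DataError("empty model frame")
    cols, names = [np.ones((n, 1))], ["Intercept"]
    blocks = {"intercept": slice(0, 1)}

    levels = sorted(frame["site_id"].astype(str).unique())
    reference = None
    if len(levels) >= 2:
        reference = spec.site_reference if spec.site_reference in levels else levels[0]
        if reference != spec.site_reference:
            log.warning("reference site %r not observed; using %r",
                        spec.site_reference, reference)
        others = [s for s in levels if s != reference]
        D = np.column_stack([
            (frame["site_id"].astype(str) == s).to_numpy(float) for s in others
        ])
        blocks["site"] = slice(cols_len := 1, cols_len + len(others))
        cols.append(D)
        names += [f"site[{s}]" for s in others]
    else:
        log.warning("fewer than 2 sites; site factor dropped")

    p0 = sum(c.shape[1] for c in cols)
    Xlin = frame[list(spec.covariates)].to_numpy(float)
    means = Xlin.mean(axis=0)
    cols.append(Xlin - means)  # centered internally; un-done on the raw scale
    names += list(spec.covariates)
    blocks["linear"] = slice(p0, p0 + Xlin.shape[1])
    p = p0 + Xlin.shape[1]

    penalties, bases = [], {}
    st = frame["ST"].to_numpy(float) if "ST" in frame.columns else None
    doy = frame["DOY"].to_numpy(float) if "DOY" in frame.columns else None
    if spec.f1 is not None:
        b1 = build_cyclic_basis(st, spec.f1.n_basis, spec.f1.period,
                                spec.knot_placement)
        Z1, C1 = apply_sum_to_zero(b1.evaluate(st))
        blocks["f1"] = slice(p, p + Z1.shape[1])
        penalties.append(("f1", blocks["f1"], C1.T @ b1.penalty @ C1))
        bases["f1"] = (b1, C1)
        cols.append(Z1)
        names += [f"f1.{i}" for i in range(Z1.shape[1])]
        p += Z1.shape[1]
    if spec.f2 is not None:
        b2 = build_cyclic_basis(doy, spec.f2.n_basis, spec.f2.period,
                                spec.knot_placement)
        Z2, C2 = apply_sum_to_zero(b2.evaluate(doy))
        blocks["f2"] = slice(p, p + Z2.shape[1])
        penalties.append(("f2", blocks["f2"], C2.T @ b2.penalty @ C2))
        bases["f2"] = (b2, C2)
        cols.append(Z2)
        names += [f"f2.{i}" for i in range(Z2.shape[1])]
        p += Z2.shape[1]
    if spec.f3 is not None:
        if spec.f1 is None or spec.f2 is None:
            raise ConfigError("f3 interaction requires both f1 and f2 margins")
        bst = build_cyclic_basis(st, spec.f3.n_basis_st, spec.f1.period,
                                 spec.knot_placement)
        bdoy = build_cyclic_basis(doy, spec.f3.n_basis_doy, spec.f2.period,
                                  spec.knot_placement)
        tensor = build_tensor_basis(bst, bdoy, st, doy)
        ZT = tensor.evaluate(st, doy)
        blocks["f3"] = slice(p, p + ZT.shape[1])
        penalties.append(("f3_st", blocks["f3"], tensor.penalty_x))
        penalties.append(("f3_doy", blocks["f3"], tensor.penalty_y))
        bases["f3"] = tensor
        cols.append(ZT)
        names += [f"f3.{i}" for i in range(ZT.shape[1])]
        p += ZT.shape[1]

    X = np.ascontiguousarray(np.hstack(cols))
    ranges = {c: (float(frame[c].min()), float(frame[c].max()))
              for c in list(spec.covariates) + ["ST", "DOY"]
              if c in frame.columns}
    return Design(X, names, blocks, penalties, levels, reference, means,
                  bases, ranges)


@dataclass
class IRLSResult:
    beta: np.ndarray
    cov: np.ndarray          # Bayesian covariance (XtWX + S_lambda)^{-1}
    deviance: float
    edf: float
    edf_by_col: np.ndarray
    n_iter: int
    XtWX: np.ndarray


def _embed(penalties, lambdas, p):
    S = np.zeros((p, p))
    for name, sl, Sb in penalties:
        S[sl, sl] += lambdas[name] * Sb
    return S


def penalized_irls(
    X: np.ndarray,
    y: np.ndarray,
    penalties: list,
    tol: float = 1e-8,
    maxiter: int = 100,
    beta0: np.ndarray | None = None,
) -> IRLSResult:
    """Maximize the penalized Poisson quasi-log-likelihood with log link.

    ``penalties`` is a list of ``(matrix, lam)`` pairs with full-size
    matrices, or ``(name, slice, block-matrix)`` triples paired with a
    ``lambdas`` dict via :func:`_embed` (internal callers).  Convergence:
    relative penalized-deviance change below ``tol`` or ``maxiter``
    iterations, with step halving as a safeguard.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise DataError("response must be non-negative")
    n, p = X.shape
    S = np.zeros((p, p))
    for item in penalties:
        if len(item) == 2:
            M, lam = item
            S += lam * np.asarray(M, dtype=float)
        else:  # pragma: no cover - internal triple form handled by _embed
            raise ValueError("penalties must be (matrix, lambda) pairs")

    if beta0 is not None:
        beta = np.asarray(beta0, dtype=float).copy()
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
    else:
        beta = np.zeros(p)
        mu = np.maximum(y, 0.0) + max(np.mean(y), 1e-3) * 0.5 + 1e-3
        eta = np.log(mu)

    def pen_obj(dev, b):
        return dev + float(b @ S @ b)

    dev = poisson_deviance(y, mu)
    obj = pen_obj(dev, beta)
    trace = [obj]
    XtWX = None
    for it in range(1, maxiter + 1):
        w = mu
        z = eta + (y - mu) / mu
        WX = X * w[:, None]
        XtWX = X.T @ WX
        A = XtWX + S
        ridge = 1e-10 * max(np.max(np.diag(XtWX)), 1.0)
        A[np.diag_indices_from(A)] += ridge
        rhs = WX.T @ z
        try:
            cf = scipy.linalg.cho_factor(A, check_finite=False)
            beta_new = scipy.linalg.cho_solve(cf, rhs, check_finite=False)
        except np.linalg.LinAlgError:
            _raise_rank_deficient(X)
        step = 1.0
        for _ in range(30):
            cand = beta + step * (beta_new - beta)
            eta_c = np.clip(X @ cand, -_ETA_CLIP, _ETA_CLIP)
            mu_c = np.exp(eta_c)
            dev_c = poisson_deviance(y, mu_c)
            obj_c = pen_obj(dev_c, cand)
            if np.isfinite(obj_c) and obj_c <= obj + 1e-12 * (abs(obj) + 1.0):
                break
            step *= 0.5
        beta, eta, mu, dev = cand, eta_c, mu_c, dev_c
        rel = abs(obj - obj_c) / (abs(obj_c) + 0.1)
        obj = obj_c
        trace.append(obj)
        if rel < tol:
            break
    else:
        raise NumericError(
            f"penalized IRLS did not converge in {maxiter} iterations", trace
        )

    # refresh weights at the solution for covariance / edf
    w = mu
    WX = X * w[:, None]
    XtWX = X.T @ WX
    A = XtWX + S
    A[np.diag_indices_from(A)] += 1e-10 * max(np.max(np.diag(XtWX)), 1.0)
    try:
        cf = scipy.linalg.cho_factor(A, check_finite=False)
    except np.linalg.LinAlgError:
        _raise_rank_deficient(X)
    cov = scipy.linalg.cho_solve(cf, np.eye(p), check_finite=False)
    F = cov @ XtWX
    edf_by_col = np.diag(F).copy()
    return IRLSResult(beta, cov, dev, float(edf_by_col.sum()), edf_by_col,
                      it, XtWX)


def _raise_rank_deficient(X: np.ndarray):
    """Diagnose collinear columns via pivoted QR and raise."""
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    bad = piv[d < d[0] * 1e-10] if d[0] > 0 else piv
    raise NumericError(
        f"design matrix rank deficient; suspect columns {sorted(bad.tolist())}"
    )


def _irls_with_lambdas(X, y, penalties, lambdas, spec, beta0=None):
    pairs = []
    p = X.shape[1]
    Sfull = _embed(penalties, lambdas, p)
    return penalized_irls(X, y, [(Sfull, 1.0)], tol=spec.tol,
                          maxiter=spec.maxiter, beta0=beta0)


def _gcv_score(res: IRLSResult, n: int) -> float:
    denom = max(n - res.edf, 1e-3)
    return n * res.deviance / denom ** 2


def _penalty_scales(design: Design, y: np.ndarray) -> dict:
    """Initial lambda scaling so the grid is comparable across smooths.

    Each penalty's unit lambda is scaled so that the penalty and the
    information matrix of its block have comparable Frobenius norms.
    """
    mu0 = max(float(np.mean(y)), 1e-3)
    scales = {}
    for name, sl, Sb in design.penalties:
        Xb = design.X[:, sl]
        info = mu0 * (Xb.T @ Xb)
        sn = np.linalg.norm(Sb)
        scales[name] = float(np.linalg.norm(info) / sn) if sn > 0 else 1.0
    return scales


def _select_lambdas(design: Design, y: np.ndarray, spec: ModelSpec) -> dict:
    """Coordinate-descent GCV minimization over a log-spaced grid."""
    names = [nm for nm, _, _ in design.penalties]
    if not names:
        return {}
    scales = _penalty_scales(design, y)
    grid = np.asarray(spec.lambda_grid, dtype=float)
    lam_rel = {nm: 1.0 for nm in names}
    beta0 = None
    best_res = None
    for _sweep in range(spec.sweeps):
        for nm in names:
            best = (np.inf, lam_rel[nm])
            for g in grid:
                trial = dict(lam_rel)
                trial[nm] = g
                lambdas = {k: v * scales[k] for k, v in trial.items()}
                res = _irls_with_lambdas(design.X, y, design.penalties,
                                         lambdas, spec, beta0=beta0)
                beta0 = res.beta
                score = _gcv_score(res, len(y))
                if score < best[0] - 1e-12:
                    best = (score, g)
                    best_res = res
            lam_rel[nm] = best[1]
            if best[1] in (grid[0], grid[-1]):
                log.warning("GCV solution for %s at grid boundary (%.3g)",
                            nm, best[1])
    return {nm: lam_rel[nm] * scales[nm] for nm in names}


def select_smoothing(frame: pd.DataFrame, spec: ModelSpec) -> dict:
    """Data-driven smoothing parameters (absolute lambdas) for the spec."""
    if spec.method == "fixed":
        return dict(spec.fixed_lambdas or {})
    design = build_design(frame, spec)
    y = frame["y"].to_numpy(float)
    return _select_lambdas(design, y, spec)


@dataclass
class FittedGAPM:
    """A fitted penalized Poisson GAM with everything needed for inference."""

    spec: ModelSpec
    coef: np.ndarray            # raw-scale coefficients
    cov: np.ndarray             # raw-scale Bayesian covariance
    col_names: list[str]
    blocks: dict
    lambdas: dict
    deviance: float
    null_deviance: float
    edf_total: float
    edf_by_block: dict
    n_obs: int
    site_levels: list[str]
    reference: str | None
    bases: dict
    ranges: dict
    n_iter: int
    species: str | None = None

    def coef_named(self) -> pd.Series:
        return pd.Series(self.coef, index=self.col_names)


def fit_gapm(frame: pd.DataFrame, spec: ModelSpec | None = None,
             species: str | None = None) -> FittedGAPM:
    """Fit the GAPM to a model frame; bit-stable for identical inputs."""
    spec = spec or ModelSpec()
    design = build_design(frame, spec)
    y = frame["y"].to_numpy(float)
    if spec.method == "fixed":
        lambdas = dict(spec.fixed_lambdas or {})
        missing = {nm for nm, _, _ in design.penalties} - set(lambdas)
        if missing:
            raise ConfigError(f"fixed lambdas missing for {sorted(missing)}")
    else:
        lambdas = _select_lambdas(design, y, spec)
    res = _irls_with_lambdas(design.X, y, design.penalties, lambdas, spec)

    # transform internally-centered linear columns back to the raw scale
    p = design.X.shape[1]
    A = np.eye(p)
    A[0, design.blocks["linear"]] = -design.linear_means
    coef = A @ res.beta
    cov = A @ res.cov @ A.T

    ybar = float(np.mean(y))
    null_dev = poisson_deviance(y, np.full_like(y, max(ybar, 1e-12)))
    edf_by_block = {
        name: float(res.edf_by_col[sl].sum()) for name, sl in design.blocks.items()
    }
    return FittedGAPM(
        spec=spec, coef=coef, cov=cov, col_names=design.col_names,
        blocks=design.blocks, lambdas=lambdas, deviance=res.deviance,
        null_deviance=null_dev, edf_total=res.edf, edf_by_block=edf_by_block,
        n_obs=len(y), site_levels=design.site_levels,
        reference=design.reference, bases=design.bases, ranges=design.ranges,
        n_iter=res.n_iter, species=species,
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def wald_tests(fit: FittedGAPM) -> pd.DataFrame:
    """Estimates, SEs, z, two-sided p and significance stars for the
    parametric terms (intercept, site contrasts, weather coefficients)."""
    rows = []
    se_all = np.sqrt(np.maximum(np.diag(fit.cov), 0.0))
    idx = list(range(*fit.blocks["intercept"].indices(len(fit.coef))))
    if "site" in fit.blocks:
        idx += list(range(*fit.blocks["site"].indices(len(fit.coef))))
    idx += list(range(*fit.blocks["linear"].indices(len(fit.coef))))
    for i in idx:
        est, se = fit.coef[i], se_all[i]
        z = est / se if se > 0 else 0.0
        p = float(2.0 * norm.sf(abs(z))) if se > 0 else 1.0
        rows.append((fit.col_names[i], est, se, z, p, _stars(p)))
    return pd.DataFrame(rows, columns=["term", "estimate", "se", "z", "p",
                                       "stars"]).set_index("term")


def smooth_significance(fit: FittedGAPM) -> pd.DataFrame:
    """Wald chi-square tests of the smooth coefficient blocks.

    The statistic is the quadratic form of the block coefficients against
    the corresponding Bayesian covariance block, referred to a chi-square
    with the block's effective degrees of freedom.  This is a simplification
    of more refined randomized-df approximations and tends to be
    conservative for heavily penalized terms.
    """
    rows = []
    for name in ("f1", "f2", "f3"):
        if name not in fit.blocks:
            continue
        sl = fit.blocks[name]
        b = fit.coef[sl]
        V = fit.cov[sl, sl]
        if np.allclose(b, 0.0):
            stat = 0.0
        else:
            stat = float(b @ scipy.linalg.solve(V, b, assume_a="pos"))
        # floor at one df: under heavy shrinkage the block edf collapses
        # toward zero and a chi-square reference with near-zero df would
        # declare any nonzero statistic significant
        df = max(fit.edf_by_block[name], 1.0)
        p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
        rows.append((name, stat, df, p, _stars(p)))
    return pd.DataFrame(rows, columns=["smooth", "chi2", "edf", "p", "stars"]
                        ).set_index("smooth")


def deviance_explained(fit: FittedGAPM) -> float:
    """1 - deviance/null deviance: share of the deviation from the null
    (intercept-only) model captured by the fit."""
    if fit.null_deviance <= 0:
        return 0.0
    return 1.0 - fit.deviance / fit.null_deviance


_ALL_COMPONENTS = ("intercept", "site", "linear", "f1", "f2", "f3")


def predict(
    fit: FittedGAPM,
    newdata: pd.DataFrame,
    components=None,
    scale: str = "response",
) -> np.ndarray:
    """Component-selective prediction on the link or response scale."""
    if scale not in ("link", "response"):
        raise ConfigError(f"unknown scale {scale!r}")
    comps = tuple(components) if components is not None else _ALL_COMPONENTS
    unknown = set(comps) - set(_ALL_COMPONENTS)
    if unknown:
        raise ConfigError(f"unknown components {sorted(unknown)}")
    n = len(newdata)
    eta = np.zeros(n)
    for c, (lo, hi) in fit.ranges.items():
        if c in newdata.columns:
            v = newdata[c].to_numpy(float)
            span = max(hi - lo, 1e-9)
            if v.min() < lo - 0.05 * span or v.max() > hi + 0.05 * span:
                log.warning("prediction extrapolates beyond fitted range of %s", c)
    if "intercept" in comps:
        eta += fit.coef[fit.blocks["intercept"]][0]
    if "site" in comps and "site" in fit.blocks:
        site_coef = dict(zip(
            [s for s in fit.site_levels if s != fit.reference],
            fit.coef[fit.blocks["site"]],
        ))
        site_coef[fit.reference] = 0.0
        try:
            eta += newdata["site_id"].astype(str).map(site_coef).to_numpy(float)
        except (KeyError, TypeError):
            raise DataError("newdata contains sites unseen during fitting")
        if np.any(np.isnan(eta)):
            raise DataError("newdata contains sites unseen during fitting")
    if "linear" in comps:
        Xl = newdata[list(fit.spec.covariates)].to_numpy(float)
        eta += Xl @ fit.coef[fit.blocks["linear"]]
    if "f1" in comps and "f1" in fit.blocks:
        b1, C1 = fit.bases["f1"]
        eta += b1.evaluate(newdata["ST"].to_numpy(float)) @ C1 \
            @ fit.coef[fit.blocks["f1"]]
    if "f2" in comps and "f2" in fit.blocks:
        b2, C2 = fit.bases["f2"]
        eta += b2.evaluate(newdata["DOY"].to_numpy(float)) @ C2 \
            @ fit.coef[fit.blocks["f2"]]
    if "f3" in comps and "f3" in fit.blocks:
        tensor: TensorBasis = fit.bases["f3"]
        eta += tensor.evaluate(newdata["ST"].to_numpy(float),
                               newdata["DOY"].to_numpy(float)) \
            @ fit.coef[fit.blocks["f3"]]
    return np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP)) if scale == "response" else eta
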