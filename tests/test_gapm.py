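"""Penalized Poisson GAM: IRLS, GCV, inference, prediction."""

import numpy as np
import pandas as pd
import pytest

from batemerge.config import TrueModel, species_truth
from batemerge.experiments import LEAN_SPEC
from batemerge.gapm import (
    ModelSpec,
    SmoothSpec,
    _stars,
    build_design,
    deviance_explained,
    fit_gapm,
    penalized_irls,
    poisson_deviance,
    predict,
    select_smoothing,
    smooth_significance,
    wald_tests,
)
from batemerge.simulate import simulate_model_frame

LINEAR_SPEC = ModelSpec(f1=None, f2=None, f3=None, method="fixed",
                        fixed_lambdas={})


class TestPenalizedIRLS:
    def test_intercept_only_closed_form(self):
        y = np.full(100, 4.2)
        X = np.ones((100, 1))
        res = penalized_irls(X, y, [])
        assert res.beta[0] == pytest.approx(np.log(4.2), abs=1e-8)

    def test_matches_independent_glm_optimizer(self, glm_frame):
        """lambda = 0, linear terms only: coefficients within 1e-6 of an
        independent Newton maximization of the same likelihood."""
        import statsmodels.api as sm

        fit = fit_gapm(glm_frame, LINEAR_SPEC)
        X = pd.get_dummies(glm_frame.site_id, drop_first=True).astype(float)
        Xd = sm.add_constant(pd.concat(
            [X, glm_frame[list(LINEAR_SPEC.covariates)]], axis=1))
        oracle = sm.GLM(glm_frame.y, Xd,
                        family=sm.families.Poisson()).fit(tol=1e-12)
        mapping = {"Intercept": "const", "site[B]": "B", "site[C]": "C"}
        mine = fit.coef_named()
        for name in mine.index:
            assert mine[name] == pytest.approx(
                oracle.params[mapping.get(name, name)], abs=1e-6)

    def test_huge_penalty_collapses_smooth_to_constant(self):
        """lambda -> 1e9 on a smooth-only model leaves only the mean."""
        rng = np.random.default_rng(5)
        n = 2000
        st = rng.uniform(-1, 1, n)
        mu = np.exp(0.5 + np.sin(np.pi * st))
        frame = pd.DataFrame({
            "site_id": "s", "ST": st, "DOY": 50,
            "T_S": 0.0, "T_A": 0.0, "AP": 0.0, "APT": 0.0, "WS": 0.0,
            "PR": 0.0, "CC": 0.0, "y": rng.poisson(mu).astype(float),
        })
        spec = ModelSpec(f1=SmoothSpec(10, (-1.0, 1.0)), f2=None, f3=None,
                         method="fixed", fixed_lambdas={"f1": 1e9})
        fit = fit_gapm(frame, spec)
        eta = predict(fit, frame, scale="link")
        assert np.max(np.abs(eta - eta.mean())) < 1e-3

    def test_real_valued_response_accepted(self):
        """Non-integer y (min of moving averages) runs through the same
        quasi-likelihood deviance without error."""
        rng = np.random.default_rng(6)
        y = rng.poisson(3.0, 500) + rng.uniform(0, 1, 500)
        X = np.ones((500, 1))
        res = penalized_irls(X, y, [])
        assert res.beta[0] == pytest.approx(np.log(y.mean()), abs=1e-8)

    def test_all_zero_response_hits_boundary_without_crash(self):
        y = np.zeros(200)
        X = np.ones((200, 1))
        res = penalized_irls(X, y, [])
        assert res.beta[0] < -25  # intercept at the clipped boundary
        assert res.deviance == pytest.approx(0.0, abs=1e-6)

    def test_negative_response_rejected(self):
        from batemerge.errors import DataError
        with pytest.raises(DataError):
            penalized_irls(np.ones((10, 1)), np.array([-1.0] * 10), [])


class TestDeviance:
    def test_zero_at_perfect_fit(self):
        y = np.array([0.0, 1.0, 2.5, 4.0])
        assert poisson_deviance(y, np.maximum(y, 1e-12)) == pytest.approx(0.0, abs=1e-6)

    def test_explained_zero_for_intercept_only(self, glm_frame):
        spec = ModelSpec(covariates=("T_A",), f1=None, f2=None, f3=None,
                         method="fixed", fixed_lambdas={})
        frame = glm_frame.copy()
        frame["T_A"] = 0.0  # degenerate covariate: effectively intercept-only
        frame = frame.drop(columns="site_id").assign(site_id="s")
        fit = fit_gapm(frame, spec)
        assert deviance_explained(fit) == pytest.approx(0.0, abs=1e-6)

    def test_monotone_under_nested_covariates(self, glm_frame):
        des = []
        for covs in (("T_A",), ("T_A", "WS"), ("T_A", "WS", "AP")):
            spec = ModelSpec(covariates=covs, f1=None, f2=None, f3=None,
                             method="fixed", fixed_lambdas={})
            des.append(deviance_explained(fit_gapm(glm_frame, spec)))
        assert des[0] <= des[1] + 1e-10 <= des[2] + 2e-10


class TestSmoothingSelection:
    def test_fixed_mode_bypasses_search(self, glm_frame):
        spec = ModelSpec(f1=None, f2=None, f3=None, method="fixed",
                         fixed_lambdas={"f1": 3.14})
        assert select_smoothing(glm_frame, spec) == {"f1": 3.14}

    def test_gcv_prefers_lighter_penalty_for_wiggly_truth(self):
        """The selected DOY penalty is smaller when the true seasonal
        effect is strongly wiggly than when it is absent."""
        base = species_truth("M_myotis")
        # raise the intercept so hourly counts (~2/h) inform the smooth
        wiggly = TrueModel(alpha=base.alpha + 3.0,
                           site_effects=base.site_effects, beta=base.beta,
                           f1_truth=base.f1_truth, f2_truth=base.f2_truth)
        flat = TrueModel(alpha=base.alpha + 3.0,
                         site_effects=base.site_effects, beta=base.beta,
                         f1_truth=base.f1_truth)
        frames = {
            "wiggly": simulate_model_frame(wiggly, 8000, seed=21),
            "flat": simulate_model_frame(flat, 8000, seed=21),
        }
        from batemerge.gapm import _penalty_scales
        lam = {}
        for k, v in frames.items():
            design = build_design(v, LEAN_SPEC)
            scale = _penalty_scales(design, v["y"].to_numpy(float))["f2"]
            lam[k] = select_smoothing(v, LEAN_SPEC)["f2"] / scale
        assert lam["wiggly"] < lam["flat"]

    def test_gcv_returns_grid_argmin(self, smooth_fit):
        """The returned lambda scores no worse than every other grid point
        along its own coordinate."""
        from batemerge.gapm import _gcv_score, _irls_with_lambdas, _penalty_scales

        truth, frame, fit = smooth_fit
        design = build_design(frame, LEAN_SPEC)
        y = frame["y"].to_numpy(float)
        chosen = fit.lambdas
        score0 = _gcv_score(_irls_with_lambdas(
            design.X, y, design.penalties, chosen, LEAN_SPEC), len(y))
        scales = _penalty_scales(design, y)
        for g in LEAN_SPEC.lambda_grid:
            trial = dict(chosen)
            trial["f2"] = g * scales["f2"]
            s = _gcv_score(_irls_with_lambdas(
                design.X, y, design.penalties, trial, LEAN_SPEC), len(y))
            assert score0 <= s + 1e-6 * abs(s)


class TestInference:
    @pytest.mark.parametrize("p,stars", [
        (0.2, ""), (0.04, "*"), (0.009, "**"), (0.0009, "***"),
    ])
    def test_star_thresholds(self, p, stars):
        assert _stars(p) == stars

    def test_wald_zero_estimate_p_one(self, glm_frame):
        fit = fit_gapm(glm_frame, LINEAR_SPEC)
        w = wald_tests(fit)
        # z = est/se and p = 2*Phi(-|z|): spot-check the identity
        from scipy.stats import norm
        row = w.loc["T_A"]
        assert row["p"] == pytest.approx(2 * norm.sf(abs(row["z"])), rel=1e-9)
        assert row["z"] == pytest.approx(row["estimate"] / row["se"], rel=1e-9)

    def test_smooth_significance_strong_seasonal_term(self, smooth_fit):
        _, _, fit = smooth_fit
        sig = smooth_significance(fit)
        assert sig.loc["f2", "p"] < 0.001
        assert sig.loc["f1", "p"] < 0.001
        assert (sig["chi2"] >= 0).all()


class TestPredict:
    def test_component_additivity_on_link_scale(self, smooth_fit):
        _, frame, fit = smooth_fit
        total = predict(fit, frame, scale="link")
        parts = sum(
            predict(fit, frame, components=(c,), scale="link")
            for c in ("intercept", "site", "linear", "f1", "f2")
        )
        assert np.allclose(total, parts, atol=1e-10)

    def test_f2_component_depends_on_doy_only(self, smooth_fit):
        _, frame, fit = smooth_fit
        a = frame.head(50).copy()
        b = a.copy()
        b[["T_S", "T_A", "AP", "APT", "WS", "PR", "CC"]] += 5.0
        va = predict(fit, a, components=("f2",), scale="link")
        vb = predict(fit, b, components=("f2",), scale="link")
        assert np.array_equal(va, vb)

    def test_mean_matching_at_canonical_link(self, smooth_fit):
        """Sum of response-scale training predictions ~ sum of y (score
        equation of the Poisson log-link at the optimum)."""
        _, frame, fit = smooth_fit
        mu = predict(fit, frame, scale="response")
        assert mu.sum() == pytest.approx(frame["y"].sum(), rel=0.005)


class TestStability:
    def test_refit_is_bit_stable(self, glm_frame):
        a = fit_gapm(glm_frame, LINEAR_SPEC)
        b = fit_gapm(glm_frame, LINEAR_SPEC)
        assert np.array_equal(a.coef, b.coef)
        assert np.array_equal(a.cov, b.cov)

    def test_single_site_drops_factor(self, glm_frame):
        frame = glm_frame.copy()
        frame["site_id"] = "only"
        fit = fit_gapm(frame, LINEAR_SPEC)
        assert "site" not in fit.blocks

    def test_self_consistency_of_deviance_explained(self, smooth_fit):
        """Refitting data simulated from a fitted model reproduces the
        generating fit's deviance explained within 5 points."""
        _, frame, fit = smooth_fit
        mu = predict(fit, frame, scale="response")
        frame2 = frame.copy()
        frame2["y"] = np.random.default_rng(17).poisson(mu).astype(float)
        fit2 = fit_gapm(frame2, LEAN_SPEC)
        assert abs(deviance_explained(fit2)
                   - deviance_explained(fit)) < 0.05
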