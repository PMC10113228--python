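"""Cyclic cubic spline basis, penalty, constraints and tensor product."""

import numpy as np
import pytest

from batemerge.splines import (
    CyclicBasis,
    apply_sum_to_zero,
    build_cyclic_basis,
    build_tensor_basis,
    penalty_matrix,
)


@pytest.fixture(scope="module")
def basis_and_sample():
    rng = np.random.default_rng(0)
    x = rng.uniform(0.0, 2.0, 2000)
    return build_cyclic_basis(x, 12, (0.0, 2.0)), x


def _d1_onesided(f, x0, h, sign):
    """One-sided first derivative, 4-point stencil: exact for cubics."""
    s = sign
    f0, f1, f2, f3 = (f(np.array([x0 + s * k * h]))[0] for k in range(4))
    return s * (-11 * f0 + 18 * f1 - 9 * f2 + 2 * f3) / (6 * h)


def _d2_onesided(f, x0, h, sign):
    """One-sided second derivative, 4-point stencil: exact for cubics."""
    f0, f1, f2, f3 = (f(np.array([x0 + sign * k * h]))[0] for k in range(4))
    return (2 * f0 - 5 * f1 + 4 * f2 - f3) / h ** 2


class TestCyclicBasis:
    def test_constants_exactly_representable(self, basis_and_sample):
        basis, x = basis_and_sample
        X = basis.evaluate(x)
        coef, *_ = np.linalg.lstsq(X, np.full(len(x), 3.7), rcond=None)
        assert np.max(np.abs(X @ coef - 3.7)) < 1e-10

    def test_rows_identical_at_period_endpoints(self, basis_and_sample):
        basis, _ = basis_and_sample
        assert np.array_equal(basis.evaluate([0.0]), basis.evaluate([2.0]))

    def test_seam_continuity_value_first_second_derivative(self, basis_and_sample):
        """Value, f' and f'' match at the period seam to 1e-6 by finite
        differences (stencils are cubic-exact, so only genuine mismatch
        and round-off remain)."""
        basis, _ = basis_and_sample
        h = 1e-3

        def f(t):
            return basis.evaluate(t)

        for col in range(basis.n_basis):
            g = lambda t: f(t)[:, col]
            assert abs(g(np.array([0.0]))[0] - g(np.array([2.0]))[0]) < 1e-12
            d1r = _d1_onesided(g, 0.0, h, +1)
            d1l = _d1_onesided(g, 2.0, h, -1)
            assert abs(d1r - d1l) < 1e-6
            d2r = _d2_onesided(g, 0.0, h, +1)
            d2l = _d2_onesided(g, 2.0, h, -1)
            assert abs(d2r - d2l) < 1e-6

    def test_sine_recovery_against_dense_lsq_oracle(self, basis_and_sample):
        basis, x = basis_and_sample
        y = np.sin(2 * np.pi * x / 2.0)
        coef, *_ = np.linalg.lstsq(basis.evaluate(x), y, rcond=None)
        grid = np.linspace(0.0, 2.0, 5001)
        err = np.max(np.abs(basis.evaluate(grid) @ coef - np.sin(np.pi * grid)))
        assert err < 0.01

    def test_nbasis_exceeding_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            build_cyclic_basis(np.array([0.1, 0.5, 0.9]), 10, (0.0, 1.0))

    def test_nbasis_minimum(self):
        with pytest.raises(ValueError):
            build_cyclic_basis(np.linspace(0, 1, 50), 3, (0.0, 1.0))


class TestPenalty:
    def test_constant_in_null_space(self, basis_and_sample):
        basis, _ = basis_and_sample
        S = penalty_matrix(basis)
        c = np.ones(basis.n_basis)
        assert abs(c @ S @ c) < 1e-7 * np.linalg.norm(S)

    def test_symmetric_psd(self, basis_and_sample):
        basis, _ = basis_and_sample
        S = penalty_matrix(basis)
        assert np.array_equal(S, S.T)
        ev = np.linalg.eigvalsh(S)
        assert ev.min() > -1e-8 * max(ev.max(), 1.0)

    def test_quadratic_form_matches_numeric_curvature_integral(
            self, basis_and_sample):
        """Penalty equals the numerically integrated squared second
        derivative of the fitted spline (trapezoid oracle)."""
        basis, x = basis_and_sample
        coef, *_ = np.linalg.lstsq(basis.evaluate(x), np.sin(np.pi * x),
                                   rcond=None)
        tt = np.linspace(0.0, 2.0, 40001)
        vals = basis.evaluate(tt) @ coef
        d2 = np.gradient(np.gradient(vals, tt), tt)
        oracle = np.trapezoid(d2[100:-100] ** 2, tt[100:-100])
        quad = coef @ basis.penalty @ coef
        assert quad == pytest.approx(oracle, rel=0.01)

    def test_wigglier_function_pays_more(self, basis_and_sample):
        basis, x = basis_and_sample
        S = basis.penalty
        smooth, *_ = np.linalg.lstsq(basis.evaluate(x), np.sin(np.pi * x),
                                     rcond=None)
        wiggly, *_ = np.linalg.lstsq(basis.evaluate(x), np.sin(3 * np.pi * x),
                                     rcond=None)
        assert wiggly @ S @ wiggly > smooth @ S @ smooth


class TestSumToZero:
    def test_centered_columns_sum_to_zero_and_rank_drop(self, basis_and_sample):
        basis, x = basis_and_sample
        B = basis.evaluate(x)
        Z, C = apply_sum_to_zero(B)
        assert np.max(np.abs(Z.sum(axis=0))) < 1e-8
        assert C.shape == (basis.n_basis, basis.n_basis - 1)
        assert np.linalg.matrix_rank(B) - np.linalg.matrix_rank(Z) == 1

    def test_fit_changes_only_by_constant(self, basis_and_sample):
        basis, x = basis_and_sample
        B = basis.evaluate(x)
        y = np.sin(np.pi * x) + 0.3
        Z, C = apply_sum_to_zero(B)
        raw, *_ = np.linalg.lstsq(B, y, rcond=None)
        cen, *_ = np.linalg.lstsq(Z, y, rcond=None)
        diff = B @ raw - Z @ cen
        assert np.std(diff) < 1e-8  # constant offset only


class TestTensor:
    @pytest.fixture(scope="class")
    def crossed(self):
        st = np.linspace(-1.0, 1.0, 40, endpoint=False)
        doy = np.linspace(0.0, 136.0, 35)
        gx, gy = np.meshgrid(st, doy)
        x, y = gx.ravel(), gy.ravel()
        b_st = build_cyclic_basis(x, 5, (-1.0, 1.0))
        b_doy = build_cyclic_basis(y, 5, (0.0, 366.0))
        return build_tensor_basis(b_st, b_doy, x, y), x, y

    def test_column_count(self, crossed):
        tensor, x, y = crossed
        assert tensor.evaluate(x, y).shape[1] == 4 * 4 == tensor.n_columns

    def test_pure_margin_function_excluded(self, crossed):
        """A function of ST alone has (numerically) no projection on the
        main-effects-excluded interaction space over a crossed grid."""
        tensor, x, y = crossed
        M = tensor.evaluate(x, y)
        h = np.sin(np.pi * x)
        coef, *_ = np.linalg.lstsq(M, h, rcond=None)
        assert np.linalg.norm(M @ coef) < 1e-8 * np.linalg.norm(h)

    def test_separable_product_representable(self, crossed):
        tensor, x, y = crossed
        f = np.sin(np.pi * x)
        g = np.sin(2 * np.pi * y / 366.0) - np.mean(np.sin(2 * np.pi * y / 366.0))
        target = (f - f.mean()) * g
        M = tensor.evaluate(x, y)
        coef, *_ = np.linalg.lstsq(M, target, rcond=None)
        resid = np.linalg.norm(M @ coef - target) / np.linalg.norm(target)
        assert resid < 0.05

    def test_penalties_psd_on_random_coefficients(self, crossed, rng):
        tensor, _, _ = crossed
        for _ in range(20):
            v = rng.normal(size=tensor.n_columns)
            assert v @ tensor.penalty_x @ v >= -1e-10
            assert v @ tensor.penalty_y @ v >= -1e-10


def test_heavy_penalty_limit_fits_weighted_mean():
    """As lambda -> infinity a penalized LS fit on the cyclic basis
    collapses to the sample mean (the penalty null space)."""
    rng = np.random.default_rng(3)
    x = rng.uniform(0.0, 2.0, 500)
    y = np.sin(np.pi * x) + rng.normal(0, 0.1, 500)
    basis = build_cyclic_basis(x, 10, (0.0, 2.0))
    B = basis.evaluate(x)
    lam = 1e12
    coef = np.linalg.solve(B.T @ B + lam * basis.penalty, B.T @ y)
    fitted = B @ coef
    assert np.max(np.abs(fitted - y.mean())) < 1e-3
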