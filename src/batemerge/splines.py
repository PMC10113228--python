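"""Cyclic cubic regression splines, penalties, constraints and tensor products.

A cyclic cubic regression spline on knots ``x_0 < ... < x_k`` (with ``x_k``
identified with ``x_0 + period``) is parameterized by its values at the
``k`` distinct knots.  Writing ``f_j = f(x_j)`` and ``g_j = f''(x_j)``,
continuity of the second derivative of the piecewise cubic interpolant
gives the cyclic tridiagonal system ``B g = D f``; the interpolant is then
linear in ``f`` and the usual wiggliness penalty is exact:

    integral f''(x)^2 dx = g' B g = f' D' B^{-1} D f.

Because coefficients are function values, the constant function is exactly
representable and lies in the penalty null space, and value, first and
second derivatives match automatically at the two period endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg


@dataclass
class CyclicBasis:
    """Cyclic cubic regression spline basis over one period.

    ``knots`` has length ``n_basis + 1``: the last knot is the wrap point,
    identified with the first.  ``penalty`` is the exact integrated squared
    second derivative quadratic form on the coefficient scale.
    """

    knots: np.ndarray
    _gamma: np.ndarray = field(repr=False)  # B^{-1} D: maps values -> 2nd derivs
    penalty: np.ndarray = field(repr=False)

    @property
    def n_basis(self) -> int:
        return len(self.knots) - 1

    @property
    def period(self) -> float:
        return float(self.knots[-1] - self.knots[0])

    def evaluate(self, x) -> np.ndarray:
        """Basis matrix rows for arbitrary x (wrapped into the period)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        k = self.n_basis
        lo = self.knots[0]
        xw = lo + np.mod(x - lo, self.period)
        j = np.clip(np.searchsorted(self.knots, xw, side="right") - 1, 0, k - 1)
        h = self.knots[j + 1] - self.knots[j]
        dr = self.knots[j + 1] - xw  # distance to right knot
        dl = xw - self.knots[j]      # distance to left knot
        am, ap = dr / h, dl / h
        cm = (dr ** 3 / h - h * dr) / 6.0
        cp = (dl ** 3 / h - h * dl) / 6.0
        jn = (j + 1) % k
        X = cm[:, None] * self._gamma[j, :] + cp[:, None] * self._gamma[jn, :]
        rows = np.arange(len(x))
        X[rows, j] += am
        X[rows, jn] += ap
        return X

    def to_dict(self) -> dict:
        return {"knots": self.knots.tolist()}

    @classmethod
    def from_knots(cls, knots: np.ndarray) -> "CyclicBasis":
        knots = np.asarray(knots, dtype=float)
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        k = len(knots) - 1
        h = np.diff(knots)  # h_j = x_{j+1} - x_j, j = 0..k-1 (cyclic: h_{-1}=h_{k-1})
        B = np.zeros((k, k))
        D = np.zeros((k, k))
        for j in range(k):
            hm = h[j - 1]  # interval ending at knot j (cyclic)
            hp = h[j]      # interval starting at knot j
            jm, jp = (j - 1) % k, (j + 1) % k
            B[j, jm] += hm / 6.0
            B[j, j] += (hm + hp) / 3.0
            B[j, jp] += hp / 6.0
            D[j, jm] += 1.0 / hm
            D[j, j] += -1.0 / hm - 1.0 / hp
            D[j, jp] += 1.0 / hp
        gamma = scipy.linalg.solve(B, D)
        S = D.T @ gamma
        S = 0.5 * (S + S.T)  # symmetrize against round-off
        return cls(knots=knots, _gamma=gamma, penalty=S)


def build_cyclic_basis(
    x,
    n_basis: int,
    period_range: tuple[float, float],
    placement: str = "quantile",
) -> CyclicBasis:
    """Construct a cyclic basis with knots placed from the sample ``x``.

    Knots sit at sample quantiles within ``period_range`` (first knot at the
    lower end, wrap at the upper end); if the quantiles collapse (heavily
    tied data) uniform spacing is used instead.
    """
    lo, hi = map(float, period_range)
    if hi <= lo:
        raise ValueError("period_range must satisfy hi > lo")
    if n_basis < 4:
        raise ValueError("n_basis must be >= 4")
    x = np.asarray(x, dtype=float)
    if placement == "quantile" and len(np.unique(x)) < n_basis:
        raise ValueError(
            f"n_basis={n_basis} exceeds the number of distinct sample values"
        )
    if placement == "uniform":
        knots = np.linspace(lo, hi, n_basis + 1)
    elif placement == "quantile":
        # n_basis knots at quantiles, excluding the upper endpoint so the
        # wrap interval [last knot, hi] keeps a regular width
        probs = np.linspace(0.0, 1.0, n_basis + 1)[:-1]
        qs = np.quantile(x, probs)
        knots = np.concatenate([qs, [hi]])
        knots[0] = lo
        if np.any(np.diff(knots) <= 1e-6 * (hi - lo)):
            knots = np.linspace(lo, hi, n_basis + 1)
    else:
        raise ValueError(f"unknown knot placement {placement!r}")
    return CyclicBasis.from_knots(knots)


def penalty_matrix(basis: CyclicBasis) -> np.ndarray:
    """The integrated-squared-second-derivative penalty (symmetric PSD)."""
    return basis.penalty


def apply_sum_to_zero(
    basis_matrix: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Center a basis so fitted smooths sum to zero over the sample.

    Returns ``(Z, C)`` where ``Z = B @ C`` is the centered basis (one fewer
    column) and ``C`` maps constrained coefficients back to the original
    coefficient scale.  The single linear constraint removes the confound
    with the model intercept.
    """
    B = np.asarray(basis_matrix, dtype=float)
    w = np.ones(B.shape[0]) if weights is None else np.asarray(weights, float)
    a = B.T @ w
    # orthonormal null-space of the constraint via a full QR of a
    Q, _ = np.linalg.qr(a[:, None], mode="complete")
    C = Q[:, 1:]
    return B @ C, C


@dataclass
class TensorBasis:
    """Tensor-product interaction of two cyclic margins, main effects removed.

    Each margin is first centered (sum-to-zero over the sample); the
    interaction columns are all pairwise products of the centered marginal
    columns.  On a crossed design this makes the interaction orthogonal to
    both marginal smooth spaces and the intercept, so f1 + f2 + f3 is
    identifiable.  Two penalties (one per margin direction) control
    wiggliness anisotropically.
    """

    margin_x: CyclicBasis
    margin_y: CyclicBasis
    C_x: np.ndarray = field(repr=False)
    C_y: np.ndarray = field(repr=False)
    penalty_x: np.ndarray = field(repr=False)
    penalty_y: np.ndarray = field(repr=False)

    @property
    def n_columns(self) -> int:
        return self.C_x.shape[1] * self.C_y.shape[1]

    def evaluate(self, x, y) -> np.ndarray:
        Zx = self.margin_x.evaluate(x) @ self.C_x
        Zy = self.margin_y.evaluate(y) @ self.C_y
        # row-wise Kronecker product
        return (Zx[:, :, None] * Zy[:, None, :]).reshape(len(Zx), -1)


def build_tensor_basis(
    b_x: CyclicBasis,
    b_y: CyclicBasis,
    x,
    y,
    weights: np.ndarray | None = None,
) -> TensorBasis:
    """Main-effects-excluded tensor product of two cyclic marginal bases."""
    Bx = b_x.evaluate(x)
    By = b_y.evaluate(y)
    _, Cx = apply_sum_to_zero(Bx, weights)
    _, Cy = apply_sum_to_zero(By, weights)
    Sx = Cx.T @ b_x.penalty @ Cx
    Sy = Cy.T @ b_y.penalty @ Cy
    px, py = Cx.shape[1], Cy.shape[1]
    penalty_x = np.kron(Sx, np.eye(py))
    penalty_y = np.kron(np.eye(px), Sy)
    return TensorBasis(b_x, b_y, Cx, Cy, penalty_x, penalty_y)
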