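"""B-spline bases with second-order random-walk (difference) penalties.

The smooth terms are penalized regression splines in the Eilers–Marx style:
a B-spline basis on equidistant knots paired with a quadratic penalty on
second differences of the coefficients, the discrete analogue of a
second-order random-walk prior.  The penalty's null space is spanned by
constant and linear coefficient vectors, so infinite smoothing shrinks a
fit to a straight line.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import BSpline

from .errors import ValidationError


def rw2_penalty(m: int) -> np.ndarray:
    """Penalty ``K = D2' D2`` from the (m-2) x m second-difference operator."""
    if m < 3:
        raise ValidationError("second-difference penalty needs at least 3 coefficients")
    d2 = np.diff(np.eye(m), n=2, axis=0)
    return d2.T @ d2


def bspline_knots(lo: float, hi: float, n_basis: int, degree: int) -> np.ndarray:
    """Clamped equidistant knot vector giving exactly ``n_basis`` functions."""
    n_interior = n_basis - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def bspline_basis(
    x: np.ndarray,
    n_basis: int,
    degree: int = 3,
    domain: tuple[float, float] | None = None,
    clamp: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate an equidistant-knot B-spline basis at ``x``.

    Returns the dense ``(len(x), n_basis)`` design matrix and the knot
    vector.  Points outside the domain raise unless ``clamp`` is set, in
    which case they are evaluated at the nearest boundary.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("x contains non-finite values")
    if n_basis < degree + 1:
        raise ValidationError(f"n_basis={n_basis} too small for degree {degree}")
    if domain is None:
        lo, hi = float(np.min(x)), float(np.max(x))
    else:
        lo, hi = map(float, domain)
    if not lo < hi:
        raise ValidationError("x (or domain) is constant: no spline domain")
    if clamp:
        x = np.clip(x, lo, hi)
    elif np.any((x < lo) | (x > hi)):
        raise ValidationError(f"x outside the spline domain [{lo}, {hi}]")
    knots = bspline_knots(lo, hi, n_basis, degree)
    basis = BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()
    return basis, knots


@dataclass
class SplineBlock:
    """A smooth term: basis, difference penalty, and identifiability transform.

    ``transform`` maps constrained coefficients (one fewer than ``n_basis``)
    back to the original basis coefficients; it is ``None`` until
    :func:`apply_sum_to_zero` is called.  ``basis``/``penalty`` always refer
    to the current (possibly constrained) parameterization.
    """

    name: str
    knots: np.ndarray
    degree: int
    basis: np.ndarray
    penalty: np.ndarray
    domain: tuple[float, float]
    transform: np.ndarray | None = None

    @property
    def n_coef(self) -> int:
        return self.basis.shape[1]

    @property
    def penalty_rank(self) -> int:
        eig = np.linalg.eigvalsh(self.penalty)
        return int(np.sum(eig > 1e-9 * max(eig.max(), 1.0)))

    def raw_basis_at(self, grid: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Unconstrained basis evaluated on a grid inside the fitted domain."""
        grid = np.asarray(grid, dtype=float)
        lo, hi = self.domain
        if clamp:
            grid = np.clip(grid, lo, hi)
        elif np.any((grid < lo) | (grid > hi)):
            raise ValidationError(f"grid outside fitted domain [{lo}, {hi}]")
        return BSpline.design_matrix(grid, self.knots, self.degree, extrapolate=False).toarray()

    def basis_at(self, grid: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Basis on a grid in the current (constrained) parameterization."""
        raw = self.raw_basis_at(grid, clamp=clamp)
        return raw @ self.transform if self.transform is not None else raw


def make_spline_block(
    x: np.ndarray,
    n_basis: int,
    degree: int = 3,
    name: str = "smooth",
    domain: tuple[float, float] | None = None,
) -> SplineBlock:
    basis, knots = bspline_basis(x, n_basis, degree, domain=domain)
    return SplineBlock(
        name=name,
        knots=knots,
        degree=degree,
        basis=basis,
        penalty=rw2_penalty(n_basis),
        domain=(float(knots[0]), float(knots[-1])),
    )


def sum_to_zero_transform(constraint: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the null space of a single linear constraint row."""
    c = np.asarray(constraint, dtype=float).reshape(1, -1)
    # Householder-style: columns 2..m of Q from the QR of c' span null(c)
    q, _ = np.linalg.qr(c.T, mode="complete")
    return q[:, 1:]


def apply_sum_to_zero(block: SplineBlock, weights: np.ndarray | None = None) -> SplineBlock:
    """Reparameterize so the fitted smooth sums to zero over the observations.

    ``weights`` (default all-ones) weight the observation rows in the
    constraint ``sum_i w_i f(x_i) = 0``; the penalty is transformed
    consistently so the random-walk prior is unchanged on the original scale.
    """
    if block.transform is not None:
        raise ValidationError("block is already constrained")
    w = np.ones(block.basis.shape[0]) if weights is None else np.asarray(weights, float)
    constraint = w @ block.basis
    z = sum_to_zero_transform(constraint)
    return replace(
        block,
        basis=block.basis @ z,
        penalty=z.T @ block.penalty @ z,
        transform=z,
    )
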