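"""Cubic B-spline bases with linear extrapolation.

Both the synthetic-truth edge functions and the fitted per-edge smoothers are
elements of a cubic B-spline space on a bounded interval.  Outside the
boundary knots every function is continued linearly (value and first
derivative at the boundary), so evaluation is defined on the whole real line
and never explodes the way polynomial extrapolation of a cubic would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

DEGREE = 3


def _knot_vector(lo: float, hi: float, interior: np.ndarray) -> np.ndarray:
    if hi <= lo:
        raise ValueError(f"empty support [{lo}, {hi}]")
    interior = np.asarray(interior, dtype=float)
    if interior.size and (interior.min() <= lo or interior.max() >= hi):
        raise ValueError("interior knots must lie strictly inside the support")
    return np.concatenate([[lo] * (DEGREE + 1), np.sort(interior), [hi] * (DEGREE + 1)])


@dataclass(frozen=True)
class BSplineBasis:
    """Cubic B-spline basis on [lo, hi] with the given interior knots."""

    lo: float
    hi: float
    interior: tuple[float, ...] = ()

    @property
    def n_basis(self) -> int:
        return len(self.interior) + DEGREE + 1

    @property
    def knots(self) -> np.ndarray:
        return _knot_vector(self.lo, self.hi, np.asarray(self.interior))

    def design(self, x: np.ndarray) -> np.ndarray:
        """Design matrix (len(x) x n_basis); linear beyond the boundary knots.

        For clamped x0 = clip(x, lo, hi) the row is B(x0) + (x - x0) * B'(x0),
        which reduces to the ordinary basis inside the support.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        t = self.knots
        spl = BSpline(t, np.eye(self.n_basis), DEGREE, extrapolate=True)
        xc = np.clip(x, self.lo, self.hi)
        out = spl(xc)
        outside = xc != x
        if np.any(outside):
            out[outside] += (x[outside] - xc[outside])[:, None] * spl.derivative()(xc[outside])
        return out

    @staticmethod
    def for_df(values: np.ndarray, df: int) -> "BSplineBasis":
        """Basis whose span (less one dropped column) has ``df`` free columns.

        Interior knots sit at evenly spaced quantiles of ``values``; df=4 gives
        a single knot at the median.  Requires df >= 3 (cubic minimum once one
        column is dropped against the intercept).
        """
        if df < 3:
            raise ValueError("spline_df must be >= 3")
        values = np.asarray(values, dtype=float)
        lo, hi = float(values.min()), float(values.max())
        if hi <= lo:
            raise ValueError("degenerate (constant) values: no spline support")
        n_interior = df - DEGREE
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(values, qs)
        # nudge knots that collide with the boundary (heavily tied data)
        eps = 1e-9 * (hi - lo)
        interior = np.clip(interior, lo + eps, hi - eps)
        interior = np.unique(interior)
        return BSplineBasis(lo, hi, tuple(float(k) for k in interior))


def greville(basis: BSplineBasis) -> np.ndarray:
    """Greville abscissae; a linear f satisfies f = B @ f(greville)."""
    t = basis.knots
    return np.array([t[i + 1 : i + 1 + DEGREE].mean() for i in range(basis.n_basis)])


@dataclass(frozen=True)
class SplineFunction:
    """A concrete function f(x) = B(x) @ coef in a cubic spline space."""

    basis: BSplineBasis
    coef: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.coef) != self.basis.n_basis:
            raise ValueError("coefficient length does not match basis size")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        y = self.basis.design(np.atleast_1d(x)) @ np.asarray(self.coef)
        return float(y[0]) if scalar else y

    @staticmethod
    def from_linear(lo: float, hi: float, slope: float, intercept: float = 0.0,
                    interior: tuple[float, ...] = ()) -> "SplineFunction":
        basis = BSplineBasis(lo, hi, interior)
        g = greville(basis)
        return SplineFunction(basis, tuple(float(v) for v in slope * g + intercept))
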