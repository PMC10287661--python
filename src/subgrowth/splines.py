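"""Cubic B-spline bases with difference penalties (P-splines).

The smooth terms of the growth models — the age effect f(t) and the
sex-specific deviation smooth — are represented by cubic B-splines with
interior knots placed at quantiles of the observed ages, penalized by a
second-order difference penalty on the coefficients.  The penalty's null
space (constant + linear trends) is separated out analytically so that the
fitting engine can treat the smooth in mixed-model form: null-space columns
become unpenalized fixed effects, range-space columns carry an identity
penalty scaled by a single smoothing parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "build_spline_basis"]

_DEGREE = 3  # cubic


@dataclass(frozen=True)
class SplineBasis:
    """A cubic B-spline basis over an age span with a curvature penalty.

    Attributes
    ----------
    knots : full (padded) knot vector, in days.
    k : basis dimension (number of B-spline functions).
    penalty_order : order of the difference penalty (2 = curvature-like).
    """

    knots: np.ndarray
    k: int
    penalty_order: int = 2
    _penalty: np.ndarray = field(default=None, repr=False, compare=False)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.knots[_DEGREE]), float(self.knots[-_DEGREE - 1])

    def evaluate(self, ages) -> np.ndarray:
        """Basis design matrix, shape (len(ages), k).

        Ages must lie inside the knot span (inclusive).
        """
        t = self._check_span(ages)
        return BSpline.design_matrix(t, self.knots, _DEGREE).toarray()

    def derivative(self, ages, order: int = 1) -> np.ndarray:
        """Design matrix of basis-function derivatives (per day)."""
        t = self._check_span(ages)
        spl = BSpline(self.knots, np.eye(self.k), _DEGREE).derivative(order)
        return spl(t)

    def greville(self) -> np.ndarray:
        """Greville abscissae: the knot averages where each basis 'sits'."""
        return np.array(
            [self.knots[i + 1:i + 1 + _DEGREE].mean() for i in range(self.k)]
        )

    def penalty(self) -> np.ndarray:
        """k x k curvature penalty: second divided differences of the
        coefficients at the Greville abscissae.

        With divided (not plain) differences the penalty null space is
        exactly the functions {1, t} regardless of knot spacing, so the
        heavy-smoothing limit of a penalized fit is the straight line.
        """
        if self._penalty is not None:
            return self._penalty
        g = self.greville()
        h = np.diff(g)
        D1 = (np.diff(np.eye(self.k), axis=0)) / h[:, None]
        w = (g[2:] - g[:-2]) / 2.0
        D2 = np.diff(D1, axis=0) / np.sqrt(w)[:, None]
        pen = D2.T @ D2
        object.__setattr__(self, "_penalty", pen)
        return pen

    def _check_span(self, ages) -> np.ndarray:
        t = np.atleast_1d(np.asarray(ages, dtype=float))
        lo, hi = self.span
        eps = 1e-9 * max(1.0, abs(hi))
        if t.min() < lo - eps or t.max() > hi + eps:
            raise ValueError(
                f"age outside fitted span [{lo:g}, {hi:g}] days: "
                f"range [{t.min():g}, {t.max():g}]"
            )
        return np.clip(t, lo, hi)


def build_spline_basis(ages, k: int = 10, penalty_order: int = 2) -> SplineBasis:
    """Build a cubic B-spline basis with quantile-placed interior knots.

    Parameters
    ----------
    ages : observed ages in days; interior knots go at quantiles of the
        unique values, boundary knots at the min/max.
    k : basis dimension (>= 4); k - 4 interior knots are used.

    Raises
    ------
    ValueError if fewer than ``k`` distinct ages are available.
    """
    ages = np.asarray(ages, dtype=float)
    uniq = np.unique(ages)
    if k < 4:
        raise ValueError(f"basis dimension k={k} must be >= 4 for cubic splines")
    if uniq.size < k:
        raise ValueError(
            f"need at least k={k} distinct ages to build a {k}-dimensional "
            f"basis; got {uniq.size}"
        )
    lo, hi = uniq[0], uniq[-1]
    n_interior = k - _DEGREE - 1
    if n_interior > 0:
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(uniq, probs)
        # keep knots strictly inside and strictly increasing
        interior = np.clip(interior, lo + 1e-9, hi - 1e-9)
        interior = _make_strictly_increasing(interior, lo, hi)
    else:
        interior = np.empty(0)
    knots = np.concatenate(
        [np.full(_DEGREE + 1, lo), interior, np.full(_DEGREE + 1, hi)]
    )
    return SplineBasis(knots=knots, k=k, penalty_order=penalty_order)


def _make_strictly_increasing(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Nudge duplicated quantile knots apart (heavy ties in the ages)."""
    if x.size == 0:
        return x
    out = x.copy()
    step = (hi - lo) * 1e-6
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + step
    return np.minimum(out, hi - step)
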