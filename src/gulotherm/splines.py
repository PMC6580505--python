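"""Cubic B-spline bases with second-derivative (curvature) penalties.

Cyclic bases are built on uniform knots by wrapping the first ``degree``
B-splines onto their periodic images, so the fitted curve and its first two
derivatives match at the domain ends. The penalty is the exact integral of
products of second derivatives (2-point Gauss-Legendre per knot interval,
exact since the integrand is piecewise quadratic for cubics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

_DEGREE = 3


@dataclass(frozen=True)
class SplineBasis:
    """A k-dimensional cubic B-spline basis on [lo, hi].

    ``design(x)`` evaluates the k basis functions; ``penalty`` is the k x k
    curvature penalty matrix. For cyclic bases x is wrapped into the domain
    with period hi - lo.
    """

    knots: np.ndarray
    k: int
    cyclic: bool
    lo: float
    hi: float
    wrap: np.ndarray  # (n_extended, k) map from extended to working basis
    penalty: np.ndarray

    @property
    def period(self) -> float:
        return self.hi - self.lo

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.cyclic:
            x = self.lo + np.mod(x - self.lo, self.period)
        else:
            if np.any(x < self.lo - 1e-9) or np.any(x > self.hi + 1e-9):
                raise ValueError("x outside basis domain")
            x = np.clip(x, self.lo, self.hi)
        n_ext = len(self.knots) - _DEGREE - 1
        cols = np.empty((len(x), n_ext))
        for j in range(n_ext):
            coef = np.zeros(n_ext)
            coef[j] = 1.0
            cols[:, j] = BSpline(self.knots, coef, _DEGREE, extrapolate=False)(x)
        cols = np.nan_to_num(cols)
        return cols @ self.wrap


def build_basis(k: int, lo: float, hi: float, cyclic: bool) -> SplineBasis:
    """Construct a cubic B-spline basis of dimension ``k`` on [lo, hi]."""
    if k < 3:
        raise ValueError("basis dimension k must be >= 3")
    if hi <= lo:
        raise ValueError("need hi > lo")

    if cyclic:
        if k < 4:
            raise ValueError("cyclic cubic basis needs k >= 4")
        h = (hi - lo) / k
        # uniform knots extended degree intervals past each end
        knots = lo + h * np.arange(-_DEGREE, k + _DEGREE + 1)
        n_ext = len(knots) - _DEGREE - 1  # k + 3
        wrap = np.zeros((n_ext, k))
        for j in range(k):
            wrap[j, j] = 1.0
        for j in range(_DEGREE):
            wrap[k + j, j] = 1.0
    else:
        inner = np.linspace(lo, hi, k - 2)
        knots = np.concatenate(([lo] * _DEGREE, inner, [hi] * _DEGREE))
        n_ext = len(knots) - _DEGREE - 1  # == k
        wrap = np.eye(k)

    S_ext = _curvature_penalty(knots, n_ext, lo, hi)
    S = wrap.T @ S_ext @ wrap
    S = 0.5 * (S + S.T)
    return SplineBasis(knots, k, cyclic, float(lo), float(hi), wrap, S)


def _curvature_penalty(knots: np.ndarray, n_basis: int,
                       lo: float, hi: float) -> np.ndarray:
    """Exact integral over [lo, hi] of second-derivative products."""
    breaks = np.unique(knots[(knots >= lo - 1e-12) & (knots <= hi + 1e-12)])
    # 2-point Gauss-Legendre nodes/weights on [-1, 1]
    gl_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    gl_w = np.array([1.0, 1.0])
    S = np.zeros((n_basis, n_basis))
    d2 = []
    for j in range(n_basis):
        coef = np.zeros(n_basis)
        coef[j] = 1.0
        d2.append(BSpline(knots, coef, _DEGREE, extrapolate=False).derivative(2))
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b - a < 1e-12:
            continue
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        nodes = mid + half * gl_x
        vals = np.empty((n_basis, len(nodes)))
        for j in range(n_basis):
            vals[j] = np.nan_to_num(d2[j](nodes))
        S += half * (vals * gl_w) @ vals.T
    return S
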