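"""Fixed points, stability, saddle-node folds and bifurcation diagrams of the
coupled function-use map.

Fixed points of the coupled map satisfy F* = U* (the single-parameter
function update forces function and use to coincide at steady state), so the
fixed-point condition collapses to the scalar equation

    g(F) = sigma(b F - c) - F = 0    on [0, 1].

Stability follows from the Jacobian of the two-dimensional map

    J = [[1 - a, a], [b U*(1 - U*), 0]],

stable iff the spectral radius is below 1. The fixed-point *set* is
independent of a; only stability margins and transients depend on it.

Saddle-node (limit) points obey the tangency system {sigma(b F - c) = F,
b sigma'(b F - c) = 1}. At a fixed point sigma = F, so the tangency reduces
to b F (1 - F) = 1, i.e. b = 1 / (F (1 - F)); substituting back gives the
one-dimensional fold curve

    c(F) = 1 / (1 - F) - logit(F),

which has a single minimum c = 2 at F = 1/2 (where b = 4). Folds therefore
exist exactly when c > 2 (equivalently b > 4 at the fold), with a degenerate
cusp at (b, c, F) = (4, 2, 1/2). The continuation in b is performed on this
scalar curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .models import ModelParams, simulate_trajectory

__all__ = [
    "FixedPoint",
    "LimitPoint",
    "fixed_points",
    "limit_points",
    "bifurcation_diagram",
    "asymptotic_state",
    "CUSP",
]

#: Degenerate cusp of the fold curve: (b, c, F).
CUSP = (4.0, 2.0, 0.5)


@dataclass(frozen=True)
class FixedPoint:
    F_star: float  # = U_star
    stability: str  # {"stable", "unstable", "neutral"}
    spectral_radius: float


@dataclass(frozen=True)
class LimitPoint:
    b_lp: float
    c_lp: float
    F_lp: float


def _g(F, b, c):
    return expit(b * F - c) - F


def _spectral_radius(a: float, b: float, F_star: float) -> float:
    u = F_star  # U* = F*
    J = np.array([[1.0 - a, a], [b * u * (1.0 - u), 0.0]])
    return float(np.max(np.abs(np.linalg.eigvals(J))))


def fixed_points(
    params: ModelParams,
    tol: float = 1e-12,
    grid: int = 2000,
    neutral_band: float = 1e-6,
) -> list[FixedPoint]:
    """All roots of sigma(b F - c) = F on [0, 1], with stability labels.

    Roots are located by a sign-change scan on a uniform grid followed by
    bisection refinement (brentq); tangential near-zero touches are caught by
    a local minimum check on |g|. At least one root always exists since g is
    continuous with g(0) >= -0 and g(1) <= 1.
    """
    if not (0.0 < params.a <= 1.0):
        raise ValueError("a must lie in (0, 1]")
    b, c = params.b, params.c
    Fs = np.linspace(0.0, 1.0, grid + 1)
    gs = _g(Fs, b, c)
    roots: list[float] = []

    def add(r: float) -> None:
        if not any(abs(r - q) < 10 * max(tol, 1.0 / grid**2) for q in roots):
            roots.append(r)

    for i in range(grid):
        g0, g1 = gs[i], gs[i + 1]
        if g0 == 0.0:
            add(float(Fs[i]))
        elif g0 * g1 < 0.0:
            add(float(brentq(_g, Fs[i], Fs[i + 1], args=(b, c), xtol=tol)))
    if gs[-1] == 0.0:
        add(1.0)
    if not roots:
        # tangential root: refine the minimum of |g|
        i = int(np.argmin(np.abs(gs)))
        lo, hi = max(0.0, Fs[i] - 2.0 / grid), min(1.0, Fs[i] + 2.0 / grid)
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(lambda F: abs(_g(F, b, c)), bounds=(lo, hi), method="bounded")
        add(float(res.x))

    out = []
    for r in sorted(roots):
        rho = _spectral_radius(params.a, b, r)
        if abs(rho - 1.0) <= neutral_band:
            stab = "neutral"
        elif rho < 1.0:
            stab = "stable"
        else:
            stab = "unstable"
        out.append(FixedPoint(F_star=r, stability=stab, spectral_radius=rho))
    return out


def _fold_curve(F: float) -> float:
    """c as a function of the fold state F: c(F) = 1/(1-F) - logit(F)."""
    return 1.0 / (1.0 - F) - float(logit(F))


def limit_points(
    c: float, b_range: tuple[float, float] = (0.0, np.inf), xtol: float = 1e-12
) -> list[LimitPoint]:
    """Saddle-node folds of the fixed-point equation at a given bias c.

    Solves c(F) = c on each monotone branch of the fold curve (decreasing on
    (0, 1/2), increasing on (1/2, 1)) and maps back through
    b = 1 / (F (1 - F)). Returns folds whose b lies in ``b_range``;
    empty below the cusp (c < 2).
    """
    lo_b, hi_b = b_range
    if lo_b < 0 or hi_b <= lo_b:
        raise ValueError("b range must be positive and increasing")
    if c < 2.0:
        return []
    if c == 2.0:
        folds = [LimitPoint(b_lp=4.0, c_lp=2.0, F_lp=0.5)]
    else:
        eps = 1e-12
        folds = []
        # lower branch: F in (0, 1/2), c(F) decreasing from +inf to 2
        f_lo = brentq(lambda F: _fold_curve(F) - c, eps, 0.5 - eps, xtol=xtol)
        # upper branch: F in (1/2, 1), c(F) increasing from 2 to +inf
        f_hi = brentq(lambda F: _fold_curve(F) - c, 0.5 + eps, 1.0 - eps, xtol=xtol)
        for F in (f_lo, f_hi):
            folds.append(LimitPoint(b_lp=1.0 / (F * (1.0 - F)), c_lp=c, F_lp=float(F)))
    folds.sort(key=lambda lp: lp.b_lp)
    return [lp for lp in folds if lo_b <= lp.b_lp <= hi_b]


def asymptotic_state(
    params: ModelParams,
    F0: float,
    U0: float,
    max_steps: int = 10_000,
    tol: float = 1e-10,
) -> float:
    """Asymptotic arm function from forward simulation.

    Iterates the coupled map until the state moves by less than ``tol``
    between steps (recovery time constants can exceed the two-year
    observation window, so the horizon is long).
    """
    F, U = float(F0), float(U0)
    for _ in range(max_steps):
        F_new = (1.0 - params.a) * F + params.a * U
        U_new = float(expit(params.b * F - params.c))
        if abs(F_new - F) < tol and abs(U_new - U) < tol:
            return F_new
        F, U = F_new, U_new
    return F


def bifurcation_diagram(c_values, b_grid, a: float = 0.6) -> pd.DataFrame:
    """Fixed-point branches over a b grid for each bias value c.

    Returns a tidy frame with columns (c, b, F_star, stability,
    spectral_radius); each (c, b) cell contributes one row per branch
    (1 or 3 branches in this family).
    """
    rows = []
    for c in np.atleast_1d(np.asarray(c_values, dtype=float)):
        for b in np.atleast_1d(np.asarray(b_grid, dtype=float)):
            for fp in fixed_points(ModelParams(a=a, b=float(b), c=float(c))):
                rows.append(
                    {
                        "c": float(c),
                        "b": float(b),
                        "F_star": fp.F_star,
                        "stability": fp.stability,
                        "spectral_radius": fp.spectral_radius,
                    }
                )
    return pd.DataFrame(rows)
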