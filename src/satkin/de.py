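"""The generalized fractional-change differential equation.

Every monotone saturation curve of the family studied here satisfies a
second-order differential equation in which each term is a fractional
change: with kappa = dy/dx,

    d(kappa)/kappa = N * dy/y - M * dx/x            (integer N, M >= 1)

Integrating once gives the first-order slope law

    dy/dx = (1/C) * y^N / x^M

and for N = M = 2 a second integration yields the hyperbola
y = x / (C1 + C2*x) with C = kappa0, C1 = 1/kappa0, C2 = 1/y_sat — the
closed form implemented in :mod:`satkin.core`.  This module verifies that
identity numerically (residual form), integrates the slope law for any
(N, M), exposes the finite-difference ratio

    [ (1/2) * y'' * dx ] / [ d(y/x) ]  ->  Gamma_fr(x)   as dx -> 0,

and selects the (N, M) pair best explaining a data set by grid search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import SaturationCurve
from .data import XYDataSet
from .exceptions import DomainError, InputError, IntegrationError

__all__ = [
    "DEFamilySpec",
    "de_residual",
    "integrate_slope_form",
    "verify_solution",
    "VerificationReport",
    "eq9_ratio",
    "discriminate_family",
]

_EXP_BOUNDS = (1, 6)  # admissible integer exponents


@dataclass(frozen=True)
class DEFamilySpec:
    """One member of the fractional-change DE family.

    n_exp, m_exp : integer exponents N, M in [1, 6]
    c_const      : positive constant C of the integrated slope law
                   dy/dx = (1/C) * y^N / x^M  (for N = M = 2, C = kappa0)
    """

    n_exp: int
    m_exp: int
    c_const: float = 1.0

    def __post_init__(self):
        lo, hi = _EXP_BOUNDS
        for name, v in (("n_exp", self.n_exp), ("m_exp", self.m_exp)):
            if int(v) != v or not (lo <= v <= hi):
                raise DomainError(f"{name} must be an integer in [{lo}, {hi}], got {v!r}")
        if not np.isfinite(self.c_const) or self.c_const <= 0:
            raise DomainError(f"c_const must be finite and > 0, got {self.c_const!r}")

    def slope(self, x: float, y: float) -> float:
        """dy/dx = y^N / (C * x^M)."""
        return y ** self.n_exp / (self.c_const * x ** self.m_exp)


def de_residual(spec: DEFamilySpec, x, y, dy_dx, d2y_dx2):
    """Pointwise residual of the fractional-change DE in derivative form.

        r = y''/y' - N*(y'/y) + M/x

    r = 0 identifies (x, y, y', y'') as lying on an exact solution for
    the exponents (N, M).  Vectorized over numpy inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dy_dx = np.asarray(dy_dx, dtype=float)
    d2y_dx2 = np.asarray(d2y_dx2, dtype=float)
    for name, v in (("x", x), ("y", y), ("dy_dx", dy_dx)):
        if np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise DomainError(
                f"{name} must be strictly positive and finite "
                "(fractional changes are undefined otherwise)"
            )
    r = d2y_dx2 / dy_dx - spec.n_exp * (dy_dx / y) + spec.m_exp / x
    return float(r) if r.ndim == 0 else r


def integrate_slope_form(
    spec: DEFamilySpec,
    x0: float,
    y0: float,
    x_grid: Sequence[float],
    rtol: float = 1e-10,
    atol: float = 0.0,
) -> np.ndarray:
    """Numerically integrate dy/dx = y^N / (C * x^M) from (x0, y0).

    Returns y at each grid point; an empty grid returns array([y0]).
    The grid must be strictly increasing with every point >= x0 (points
    equal to x0 map to y0).  Integration cannot start at x = 0 because of
    the M/x singularity.
    """
    if not np.isfinite(x0) or x0 <= 0:
        raise DomainError(f"x0 must be finite and > 0, got {x0!r}")
    if not np.isfinite(y0) or y0 <= 0:
        raise DomainError(f"y0 must be finite and > 0, got {y0!r}")
    grid = np.asarray(x_grid, dtype=float)
    if grid.size == 0:
        return np.array([y0])
    if np.any(np.diff(grid) <= 0):
        raise DomainError("x_grid must be strictly increasing")
    if grid[0] < x0:
        raise DomainError("x_grid points must be >= x0")

    t_eval = grid[grid > x0]
    if atol == 0.0:
        atol = 1e-12 * max(y0, 1.0)

    def rhs(x, y):
        return [spec.slope(x, y[0])]

    if t_eval.size:
        sol = solve_ivp(
            rhs,
            (x0, float(t_eval[-1])),
            [float(y0)],
            method="DOP853",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"slope-law integration failed: {sol.message}")
        y_vals = sol.y[0]
        if np.any(y_vals <= 0) or not np.all(np.isfinite(y_vals)):
            raise IntegrationError(
                "integration left the positive quadrant (y <= 0 or non-finite)"
            )
    else:
        y_vals = np.empty(0)

    out = np.empty(grid.size)
    out[grid <= x0] = y0
    out[grid > x0] = y_vals
    return out


@dataclass(frozen=True)
class VerificationReport:
    """Outcome of verifying that a curve solves the N=M=2 equation."""

    max_abs_residual: float
    max_rel_integration_error: float
    tolerance: float = 1e-6

    @property
    def passed(self) -> bool:
        return (
            self.max_abs_residual <= self.tolerance
            and self.max_rel_integration_error <= self.tolerance
        )


def verify_solution(
    curve: SaturationCurve,
    x_grid: Sequence[float],
    derivatives: Optional[Tuple[Callable, Callable, Callable]] = None,
    tolerance: float = 1e-6,
) -> VerificationReport:
    """Check, on a grid, that the closed form solves the N=M=2 equation.

    Two independent checks:
      1. the analytic (y, y', y'') substituted into the DE residual;
      2. numerical integration of the slope law against the closed form.

    ``derivatives`` optionally overrides the analytic (y, y', y'') triple —
    a hook used as a negative control with a non-solution curve.
    """
    grid = np.asarray(x_grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0) or np.any(np.diff(grid) < 0):
        raise DomainError("x_grid must be non-empty, positive, increasing")

    if derivatives is None:
        f, df, d2f = curve.eval, curve.slope_at, curve.second_derivative_at
    else:
        f, df, d2f = derivatives

    spec = DEFamilySpec(2, 2, c_const=curve.kappa0)
    res = de_residual(spec, grid, f(grid), df(grid), d2f(grid))
    max_abs_residual = float(np.max(np.abs(np.atleast_1d(res))))

    x0 = float(grid[0])
    y_num = integrate_slope_form(spec, x0, float(f(x0)), grid)
    y_ref = np.atleast_1d(f(grid))
    max_rel = float(np.max(np.abs(y_num - y_ref) / np.abs(y_ref)))

    return VerificationReport(
        max_abs_residual=max_abs_residual,
        max_rel_integration_error=max_rel,
        tolerance=tolerance,
    )


def eq9_ratio(curve: SaturationCurve, x: float, dx: float) -> float:
    """Finite-difference ratio (change in slope)/(change in average slope).

    ratio = [(1/2) * y''(x) * dx] / [(y/x)(x+dx) - (y/x)(x)]

    Converges, first order in dx, to the free-site probability
    Gamma_fr(x); the 1/2 factor in the slope change is what makes the
    limit Gamma_fr rather than 2*Gamma_fr.
    """
    if not np.isfinite(x) or x <= 0:
        raise DomainError(f"x must be finite and > 0, got {x!r}")
    if not np.isfinite(dx) or dx <= 0:
        raise DomainError(f"dx must be finite and > 0, got {dx!r}")
    num = 0.5 * curve.second_derivative_at(x) * dx
    den = curve.eval(x + dx) / (x + dx) - curve.eval(x) / x
    return float(num / den)


def _log_slopes(x: np.ndarray, y: np.ndarray, smooth_window: int = 0):
    """Finite-difference slope estimates at interior points.

    Differencing is done in log-log space (dy/dx = (y/x) * dln y/dln x),
    which is exact for power laws and second-order accurate on the
    geometric grids typical of saturation designs; the one-sided endpoint
    estimates are discarded.  An optional centered moving-average window
    (odd size) smooths log y first.
    """
    ly = np.log(y)
    if smooth_window and smooth_window > 1:
        if smooth_window % 2 == 0:
            raise DomainError("smooth_window must be odd")
        pad = smooth_window // 2
        lpad = np.concatenate([np.repeat(ly[0], pad), ly, np.repeat(ly[-1], pad)])
        ly = np.convolve(lpad, np.ones(smooth_window) / smooth_window, mode="valid")
        y = np.exp(ly)
    dlog = np.gradient(ly, np.log(x))
    slopes = (y / x) * dlog
    return x[1:-1], y[1:-1], slopes[1:-1]


def discriminate_family(
    data: XYDataSet,
    n_range: Iterable[int] = range(1, 5),
    m_range: Iterable[int] = range(1, 5),
    smooth_window: int = 0,
) -> Tuple[DEFamilySpec, pd.DataFrame]:
    """Select the (N, M) exponent pair best reproducing a data set.

    For each candidate pair, C is fitted by least squares on the log slope
    law  log kappa = -log C + N log y - M log x  (slopes from finite
    differences), the slope law is integrated from the first data point,
    and the pair is scored by the sum of squared relative deviations.
    Ties break toward smaller N + M, then smaller N.

    Returns the winning DEFamilySpec and the full residual table.
    """
    if len(data) < 6:
        raise InputError("discriminate_family requires at least 6 points")
    if np.any(data.x <= 0) or np.any(data.y <= 0):
        raise InputError("discriminate_family requires strictly positive (x, y)")

    order = np.argsort(data.x)
    x = data.x[order]
    y = data.y[order]
    if np.any(np.diff(x) <= 0):
        # collapse duplicate x by averaging y before differencing
        df = pd.DataFrame({"x": x, "y": y}).groupby("x", as_index=False).mean()
        x, y = df["x"].to_numpy(), df["y"].to_numpy()
        if x.size < 6:
            raise InputError("fewer than 6 distinct x values")

    xs, ys, slopes = _log_slopes(x, y, smooth_window)
    pos = slopes > 0
    if np.sum(pos) < 2:
        raise InputError("too few positive slope estimates to fit the slope law")
    lx, ly, lk = np.log(xs[pos]), np.log(ys[pos]), np.log(slopes[pos])

    rows = []
    for n in n_range:
        for m in m_range:
            log_c = float(np.mean(n * ly - m * lx - lk))
            spec = DEFamilySpec(n, m, c_const=float(np.exp(log_c)))
            try:
                y_hat = integrate_slope_form(
                    spec, float(x[0]), float(y[0]), x, rtol=1e-8
                )
                score = float(np.sum(((y_hat - y) / y) ** 2))
            except (IntegrationError, OverflowError):
                score = np.inf
            rows.append(
                {"N": n, "M": m, "c_const": spec.c_const, "score": score}
            )

    table = pd.DataFrame(rows)
    # tie-break: among scores equal to the minimum, prefer smaller N+M then N
    best_score = table["score"].min()
    candidates = table[table["score"] == best_score].copy()
    candidates["nm"] = candidates["N"] + candidates["M"]
    best = candidates.sort_values(["nm", "N", "M"]).iloc[0]
    winner = DEFamilySpec(int(best["N"]), int(best["M"]), c_const=float(best["c_const"]))
    return winner, table.sort_values("score").reset_index(drop=True)
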