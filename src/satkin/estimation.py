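"""Estimation of the two empirical constants (kappa0, y_sat) from data.

Two routes are provided:

* the classical linear transform: plotting x/y against x gives a straight
  line with slope 1/y_sat and ordinate intercept 1/kappa0 (the Hanes-type
  plot), fitted by ordinary least squares;
* direct nonlinear least squares on y = x/(1/kappa0 + x/y_sat),
  log-parameterised so the positivity constraints are structural, with
  uniform, 1/y or 1/y^2 weighting.

The linear transform is always computed — it is the classical graphical
procedure and seeds the optimizer — while NLS with uniform weights is the
default reported method.  Case-resampling bootstrap supplies percentile
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from .core import SaturationCurve
from .data import XYDataSet
from .exceptions import FitFailureError, InputError

__all__ = [
    "FitResult",
    "linearize",
    "fit_linear_transform",
    "fit_nls",
    "bootstrap_ci",
]

WEIGHT_SCHEMES = ("uniform", "inverse_y", "inverse_y_squared")


@dataclass
class FitResult:
    """Estimated saturation curve with diagnostics.

    ``success`` is False when the data could not yield a valid curve
    (e.g. non-saturating data driving y_sat to infinity); in that case
    ``curve`` is None and ``message`` explains why.  Failed fits are
    explicit objects, never silently negative constants.
    """

    curve: Optional[SaturationCurve]
    method: str
    success: bool = True
    message: str = ""
    transform_slope: Optional[float] = None      # 1/y_sat estimate
    transform_intercept: Optional[float] = None  # 1/kappa0 estimate
    residuals: Optional[np.ndarray] = None       # y-space residuals
    r_squared: Optional[float] = None
    ci_kappa0: Optional[Tuple[float, float]] = None
    ci_ysat: Optional[Tuple[float, float]] = None
    ci_unavailable_reason: str = ""
    n_points_used: int = 0
    excluded_points: list = field(default_factory=list)
    weights: str = "uniform"
    data: Optional[XYDataSet] = field(default=None, repr=False)

    # -- convenience accessors ----------------------------------------

    @property
    def kappa0(self) -> float:
        self._require_success()
        return self.curve.kappa0

    @property
    def y_sat(self) -> float:
        self._require_success()
        return self.curve.y_sat

    @property
    def K(self) -> float:
        self._require_success()
        return self.curve.K

    def _require_success(self):
        if not self.success or self.curve is None:
            raise FitFailureError(f"fit failed: {self.message}")

    def bootstrap_ci(self, n_boot: int = 999, seed: int = 0) -> "FitResult":
        """Case-resampling bootstrap percentile intervals (returns a copy)."""
        return bootstrap_ci(self.data, method=self.method, n_boot=n_boot,
                            seed=seed, weights=self.weights)

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "success": self.success,
            "n_points_used": self.n_points_used,
            "excluded_points": list(map(int, self.excluded_points)),
        }
        if self.success:
            out.update(
                kappa0=self.curve.kappa0,
                y_sat=self.curve.y_sat,
                K=self.curve.K,
                r_squared=self.r_squared,
                ci_kappa0=list(self.ci_kappa0) if self.ci_kappa0 else None,
                ci_ysat=list(self.ci_ysat) if self.ci_ysat else None,
            )
        else:
            out["message"] = self.message
        return out

    def summary(self) -> str:
        """Human-readable fit summary table."""
        lines = ["Saturation curve fit", "=" * 52]
        lines.append(f"{'method':<22}{self.method}")
        lines.append(f"{'n points used':<22}{self.n_points_used}")
        if self.excluded_points:
            lines.append(f"{'excluded indices':<22}{self.excluded_points}")
        if not self.success:
            lines.append(f"FIT FAILED: {self.message}")
            return "\n".join(lines)
        xu = self.data.x_unit if self.data is not None else ""
        yu = self.data.y_unit if self.data is not None else ""
        per = f" [{yu}/{xu}]" if (xu or yu) else ""

        def fmt(name, value, ci, unit=""):
            s = f"{name:<22}{value:.6g}{unit}"
            if ci is not None:
                s += f"   95% CI [{ci[0]:.6g}, {ci[1]:.6g}]"
            return s

        lines.append(fmt("kappa0 (init. slope)", self.curve.kappa0,
                         self.ci_kappa0, per))
        lines.append(fmt("y_sat (limit)", self.curve.y_sat, self.ci_ysat,
                         f" [{yu}]" if yu else ""))
        lines.append(f"{'K = y_sat/kappa0':<22}{self.curve.K:.6g}"
                     + (f" [{xu}]" if xu else ""))
        if self.r_squared is not None:
            lines.append(f"{'R^2 (fitted scale)':<22}{self.r_squared:.6f}")
        return "\n".join(lines)

    def plot(self, ax=None, n_curve: int = 200):
        """Scatter of the data with the fitted curve overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.data is not None:
            ax.plot(self.data.x, self.data.y, "o", label="data")
        if self.success and self.data is not None:
            xg = np.linspace(0, float(self.data.x.max()) * 1.05, n_curve)
            ax.plot(xg, self.curve.eval(xg), "-", label="fit")
            ax.axhline(self.curve.y_sat, ls="--", lw=0.8, color="grey")
        ax.set_xlabel(self.data.x_unit or "x" if self.data else "x")
        ax.set_ylabel(self.data.y_unit or "y" if self.data else "y")
        ax.legend()
        return ax


def linearize(data: XYDataSet):
    """Transform (x, y) to (x, x/y): the straight-line form of the model.

    Points with x = 0 are excluded (the transform carries no information
    there) and reported; y <= 0 at x > 0 raises InputError naming the
    index.  Returns (x_used, x_over_y, excluded_indices).
    """
    bad_y = (data.x > 0) & (data.y <= 0)
    if np.any(bad_y):
        idx = int(np.argmax(bad_y))
        raise InputError(
            f"transform undefined: y <= 0 at index {idx} (x = {data.x[idx]!r})"
        )
    keep = data.x > 0
    excluded = np.nonzero(~keep)[0].tolist()
    x = data.x[keep]
    if np.unique(x).size < 3:
        raise InputError("fewer than 3 usable points for the linear transform")
    return x, x / data.y[keep], excluded


def _r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - fitted) ** 2))
    ss_tot = float(np.sum((observed - np.mean(observed)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def fit_linear_transform(data: XYDataSet) -> FitResult:
    """Estimate (kappa0, y_sat) by OLS on the (x, x/y) plot.

    kappa0 = 1/intercept and y_sat = 1/slope, exactly; the fitted line
    and the reported curve are the same object algebraically.
    """
    x, t, excluded = linearize(data)
    slope, intercept = np.polyfit(x, t, 1)

    base = dict(
        method="linear_transform",
        transform_slope=float(slope),
        transform_intercept=float(intercept),
        n_points_used=int(x.size),
        excluded_points=excluded,
        data=data,
    )
    if slope <= 0 or intercept <= 0:
        return FitResult(
            curve=None,
            success=False,
            message=(
                "non-positive transform estimates "
                f"(slope={slope:.3g}, intercept={intercept:.3g}): data do "
                "not saturate or are noise-dominated"
            ),
            **base,
        )
    curve = SaturationCurve(
        kappa0=1.0 / intercept, y_sat=1.0 / slope,
        x_unit=data.x_unit, y_unit=data.y_unit,
    )
    return FitResult(
        curve=curve,
        residuals=data.y - curve.eval(data.x),
        r_squared=_r_squared(t, slope * x + intercept),
        **base,
    )


def fit_nls(
    data: XYDataSet,
    init: Optional[SaturationCurve] = None,
    weights: str = "uniform",
) -> FitResult:
    """Nonlinear least squares for (kappa0, y_sat) in y-space.

    Parameters are fitted on the log scale, so the positivity constraint
    is built in.  ``weights`` selects residual scaling: uniform, 1/y
    (inverse_y) or 1/y^2 (inverse_y_squared); the latter approximates
    relative-error loss appropriate under proportional noise.
    """
    if weights not in WEIGHT_SCHEMES:
        raise InputError(f"weights must be one of {WEIGHT_SCHEMES}, got {weights!r}")
    data.require_fittable()
    if np.any((data.x > 0) & (data.y <= 0)):
        idx = int(np.argmax((data.x > 0) & (data.y <= 0)))
        raise InputError(f"y must be > 0 where x > 0; offending index {idx}")
    x, y = data.x, data.y

    transform_slope = transform_intercept = None
    if init is None:
        lt = fit_linear_transform(data)
        transform_slope, transform_intercept = lt.transform_slope, lt.transform_intercept
        if lt.success:
            init = lt.curve
        else:
            pos = x > 0
            x1 = float(np.min(x[pos]))
            y1 = float(y[x == x1][0])
            init = SaturationCurve(kappa0=y1 / x1, y_sat=1.2 * float(np.max(y)))

    # origin points (y = 0) take the weight of the smallest positive y
    y_floor = np.maximum(y, np.min(y[y > 0]))
    w = {
        "uniform": np.ones_like(y),
        "inverse_y": 1.0 / y_floor,
        "inverse_y_squared": 1.0 / y_floor**2,
    }[weights]
    sw = np.sqrt(w)

    def resid(theta):
        k0, ys = np.exp(theta)
        K = ys / k0
        return sw * (y - ys * x / (K + x))

    sol = least_squares(
        resid,
        x0=np.log([init.kappa0, init.y_sat]),
        method="lm",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    base = dict(
        method="nls",
        weights=weights,
        transform_slope=transform_slope,
        transform_intercept=transform_intercept,
        n_points_used=int(x.size),
        excluded_points=[],
        data=data,
    )
    if not sol.success:
        return FitResult(curve=None, success=False,
                         message=f"optimizer did not converge: {sol.message}",
                         **base)
    k0, ys = np.exp(sol.x)
    if not (np.isfinite(k0) and np.isfinite(ys)) or k0 <= 0 or ys <= 0:
        return FitResult(curve=None, success=False,
                         message="optimizer returned non-positive constants",
                         **base)
    curve = SaturationCurve(kappa0=float(k0), y_sat=float(ys),
                            x_unit=data.x_unit, y_unit=data.y_unit)
    fitted = curve.eval(x)
    return FitResult(
        curve=curve,
        residuals=y - fitted,
        r_squared=_r_squared(y, fitted),
        **base,
    )


def _fit(data: XYDataSet, method: str, weights: str) -> FitResult:
    if method == "linear_transform":
        return fit_linear_transform(data)
    if method == "nls":
        return fit_nls(data, weights=weights)
    raise InputError(f"unknown method {method!r}")


def bootstrap_ci(
    data: XYDataSet,
    method: str = "nls",
    n_boot: int = 999,
    seed: int = 0,
    weights: str = "uniform",
    alpha: float = 0.05,
) -> FitResult:
    """Case-resampling bootstrap percentile intervals for (kappa0, y_sat).

    Deterministic given ``seed``.  If more than 20% of resamples fail to
    fit, intervals are reported as unavailable with a diagnostic.
    """
    if n_boot < 100:
        raise InputError("n_boot must be >= 100")
    base = _fit(data, method, weights)
    base._require_success()

    rng = np.random.default_rng(seed)
    n = len(data)
    k0s, yss, failures = [], [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            sample = XYDataSet(
                x=data.x[idx], y=data.y[idx],
                x_unit=data.x_unit, y_unit=data.y_unit,
            )
            fit = _fit(sample, method, weights)
        except (InputError, FitFailureError):
            failures += 1
            continue
        if not fit.success:
            failures += 1
            continue
        k0s.append(fit.curve.kappa0)
        yss.append(fit.curve.y_sat)

    if failures > 0.2 * n_boot:
        return replace(
            base,
            ci_unavailable_reason=(
                f"{failures}/{n_boot} bootstrap resamples failed to fit; "
                "intervals unavailable"
            ),
        )
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    return replace(
        base,
        ci_kappa0=(float(np.percentile(k0s, lo)), float(np.percentile(k0s, hi))),
        ci_ysat=(float(np.percentile(yss, lo)), float(np.percentile(yss, hi))),
    )
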