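"""Closed-form hyperbolic saturation curve and its derived quantities.

The central object is :class:`SaturationCurve`, the two-constant relation

    y(x) = x / (1/kappa0 + x/y_sat) = y_sat * x / (K + x),  K = y_sat/kappa0

parameterised by the two directly measurable empirical constants of any
saturation experiment: the initial slope ``kappa0`` (dy/dx as x -> 0) and
the limiting value ``y_sat`` (the asymptote at saturation).  The
half-saturation constant K is a *derived* ratio, not a parameter.

The probabilistic reading of the curve is exposed through ``gamma_free``
and ``gamma_bound``: at any x, the probability that the interactive site
(binding site, catalytic site, receptor, predator) is free is

    Gamma_fr(x) = K / (K + x),    Gamma_bd(x) = x / (K + x) = y(x)/y_sat

and the local slope obeys the slope law  kappa_x = kappa0 * Gamma_fr(x)^2.

All probability expressions use the algebraically stable forms K/(K+x)
and x/(K+x), which do not cancel catastrophically at extreme kappa0*x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .exceptions import DomainError

ArrayLike = Union[float, int, np.ndarray, list, tuple]

__all__ = ["SaturationCurve", "GammaPoint"]


def _validate_x(x: ArrayLike, name: str = "x") -> np.ndarray:
    """Coerce x to a float array, rejecting negative or non-finite entries.

    Raises DomainError naming the offending index.
    """
    arr = np.asarray(x, dtype=float)
    bad = ~np.isfinite(arr)
    if np.any(bad):
        idx = int(np.argmax(np.atleast_1d(bad)))
        raise DomainError(f"{name} must be finite; offending index {idx}")
    neg = arr < 0
    if np.any(neg):
        idx = int(np.argmax(np.atleast_1d(neg)))
        raise DomainError(
            f"{name} must be non-negative; offending index {idx} "
            f"(value {np.atleast_1d(arr)[idx]!r})"
        )
    return arr


def _scalar_like(result: np.ndarray, x: ArrayLike):
    if np.isscalar(x) or (isinstance(x, np.ndarray) and x.ndim == 0):
        return float(result)
    return result


@dataclass(frozen=True)
class GammaPoint:
    """Free/occupied-site probabilities and effective slope at one x."""

    x: float
    gamma_bound: float
    gamma_free: float
    kappa_x: float


@dataclass(frozen=True)
class SaturationCurve:
    """Hyperbolic saturation curve defined by its two empirical constants.

    Parameters
    ----------
    kappa0 : float
        Initial slope dy/dx at x -> 0, in y-units per x-unit.  Strictly
        positive.
    y_sat : float
        Limiting value of y at saturation (the asymptote), in y-units.
        Strictly positive.
    x_unit, y_unit : str, optional
        Opaque unit labels carried into reports; never converted.
    """

    kappa0: float
    y_sat: float
    x_unit: str = field(default="", compare=False)
    y_unit: str = field(default="", compare=False)

    def __post_init__(self):
        for name in ("kappa0", "y_sat"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise DomainError(f"{name} must be finite and > 0, got {v!r}")

    @classmethod
    def from_half_saturation(cls, k: float, y_sat: float, **units) -> "SaturationCurve":
        """Construct from (K, y_sat); kappa0 = y_sat / K."""
        if not np.isfinite(k) or k <= 0:
            raise DomainError(f"K must be finite and > 0, got {k!r}")
        return cls(kappa0=y_sat / k, y_sat=y_sat, **units)

    # -- derived constants -------------------------------------------------

    @property
    def K(self) -> float:
        """Half-saturation constant K = y_sat / kappa0 (x-units).

        y(K) = y_sat/2 and Gamma_fr(K) = 1/2.
        """
        return self.y_sat / self.kappa0

    @property
    def c1(self) -> float:
        """Integration constant C1 = 1/kappa0 of the general solution."""
        return 1.0 / self.kappa0

    @property
    def c2(self) -> float:
        """Integration constant C2 = 1/y_sat of the general solution."""
        return 1.0 / self.y_sat

    def half_saturation(self) -> float:
        """Return K = y_sat / kappa0."""
        return self.K

    # -- curve and derivatives ---------------------------------------------

    def eval(self, x: ArrayLike):
        """Evaluate y(x) = y_sat * x / (K + x) for x >= 0."""
        arr = _validate_x(x)
        return _scalar_like(self.y_sat * arr / (self.K + arr), x)

    __call__ = eval

    def slope_at(self, x: ArrayLike):
        """Effective rate kappa_x = dy/dx = kappa0 * Gamma_fr(x)^2."""
        arr = _validate_x(x)
        gf = self.K / (self.K + arr)
        return _scalar_like(self.kappa0 * gf * gf, x)

    def second_derivative_at(self, x: ArrayLike):
        """d2y/dx2 = -2 * y_sat * K / (K + x)^3; negative everywhere."""
        arr = _validate_x(x)
        return _scalar_like(-2.0 * self.y_sat * self.K / (self.K + arr) ** 3, x)

    # -- site probabilities ------------------------------------------------

    def gamma_free(self, x: ArrayLike):
        """Probability the interactive site is free: K / (K + x)."""
        arr = _validate_x(x)
        return _scalar_like(self.K / (self.K + arr), x)

    def gamma_bound(self, x: ArrayLike):
        """Probability the interactive site is occupied: x / (K + x)."""
        arr = _validate_x(x)
        return _scalar_like(arr / (self.K + arr), x)

    def gamma_point(self, x: float) -> GammaPoint:
        """Bundle the site probabilities and effective slope at one x."""
        return GammaPoint(
            x=float(x),
            gamma_bound=self.gamma_bound(x),
            gamma_free=self.gamma_free(x),
            kappa_x=self.slope_at(x),
        )

    def gamma_profile(self, x: ArrayLike):
        """Tabulate (x, gamma_free, gamma_bound, kappa_x) as a DataFrame."""
        import pandas as pd

        arr = np.atleast_1d(_validate_x(x)).astype(float)
        return pd.DataFrame(
            {
                "x": arr,
                "gamma_free": self.gamma_free(arr),
                "gamma_bound": self.gamma_bound(arr),
                "kappa_x": self.slope_at(arr),
            }
        )


# Module-level functional aliases mirroring the object methods.

def eval_curve(curve: SaturationCurve, x: ArrayLike):
    return curve.eval(x)


def gamma_free(curve: SaturationCurve, x: ArrayLike):
    return curve.gamma_free(x)


def gamma_bound(curve: SaturationCurve, x: ArrayLike):
    return curve.gamma_bound(x)


def slope_at(curve: SaturationCurve, x: ArrayLike):
    return curve.slope_at(x)


def second_derivative_at(curve: SaturationCurve, x: ArrayLike):
    return curve.second_derivative_at(x)


def half_saturation(curve: SaturationCurve) -> float:
    return curve.K
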