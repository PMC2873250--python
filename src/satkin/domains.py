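"""Domain adapters: name the fitted constants per saturation phenomenon.

The same two empirical constants (initial slope kappa0, limiting value
y_sat) acquire domain-specific names and derived ratios:

* ligand binding:  y_sat = (A_b)_sat total sites; K_d = y_sat/kappa0;
  k_bind = 1/K_d
* enzyme kinetics: y_sat = P_sat limiting rate; K_m = P_sat/kappa0; with
  total enzyme E_t known, k_cat = P_sat/E_t and k_bind = kappa0/E_t, so
  K_m = k_cat/k_bind (the specificity-constant identity)
* Monod growth:    y_sat = R_sat; half-saturation K = R_sat/kappa0
* functional response (Holling type II): y_sat = N_sat; K = N_sat/kappa0

``classify_inhibition`` compares paired control/inhibited fits.  An
inhibitor may lower either empirical constant but never raise one; K_m
may move either way depending on the relative effect on binding and
catalysis.  The signature table below encodes the five classical cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .core import SaturationCurve
from .estimation import FitResult
from .exceptions import DomainError

__all__ = [
    "LigandBindingReport",
    "EnzymeReport",
    "MonodReport",
    "FunctionalResponseReport",
    "InhibitionVerdict",
    "as_ligand_binding",
    "as_enzyme",
    "as_monod",
    "as_functional_response",
    "classify_inhibition",
    "INHIBITION_SIGNATURES",
]


def _curve_of(fit: Union[FitResult, SaturationCurve]) -> SaturationCurve:
    if isinstance(fit, SaturationCurve):
        return fit
    fit._require_success()
    return fit.curve


@dataclass(frozen=True)
class LigandBindingReport:
    """Ligand-binding constants: sites, dissociation constant, binding rate."""

    ab_sat: float    # total binding sites (A_b)_sat, mol/L
    kappa0: float    # initial slope (fraction of added dA bound, at A -> 0)
    k_d: float       # dissociation constant = ab_sat/kappa0, mol/L
    k_bind: float    # binding rate constant = 1/k_d
    x_unit: str = "mol/L"
    y_unit: str = "mol/L"

    def to_dict(self) -> dict:
        return {"domain": "ligand_binding", "ab_sat": self.ab_sat,
                "kappa0": self.kappa0, "k_d": self.k_d, "k_bind": self.k_bind,
                "x_unit": self.x_unit, "y_unit": self.y_unit}


@dataclass(frozen=True)
class EnzymeReport:
    """Michaelis-Menten constants; per-mole constants only when E_t is known."""

    p_sat: float            # limiting catalytic rate
    kappa0: float           # initial slope
    k_m: float              # Michaelis constant = p_sat/kappa0
    e_t: Optional[float] = None
    k_cat: Optional[float] = None   # p_sat/e_t
    k_bind: Optional[float] = None  # kappa0/e_t = k_cat/k_m
    x_unit: str = ""
    y_unit: str = ""

    def to_dict(self) -> dict:
        out = {"domain": "enzyme", "p_sat": self.p_sat, "kappa0": self.kappa0,
               "k_m": self.k_m, "x_unit": self.x_unit, "y_unit": self.y_unit}
        if self.e_t is not None:
            out.update(e_t=self.e_t, k_cat=self.k_cat, k_bind=self.k_bind)
        return out


@dataclass(frozen=True)
class MonodReport:
    """Monod chemostat constants: limiting growth rate and half-saturation."""

    r_sat: float
    kappa0: float
    k_half: float
    x_unit: str = "g/L"
    y_unit: str = "g/L/min"

    def to_dict(self) -> dict:
        return {"domain": "monod", "r_sat": self.r_sat, "kappa0": self.kappa0,
                "k_half": self.k_half, "x_unit": self.x_unit,
                "y_unit": self.y_unit}


@dataclass(frozen=True)
class FunctionalResponseReport:
    """Holling type II constants: limiting attack rate and half-saturation
    prey density."""

    n_sat: float
    kappa0: float
    k_half: float
    x_unit: str = "prey/area"
    y_unit: str = "prey/time"

    def to_dict(self) -> dict:
        return {"domain": "functional_response", "n_sat": self.n_sat,
                "kappa0": self.kappa0, "k_half": self.k_half,
                "x_unit": self.x_unit, "y_unit": self.y_unit}


def as_ligand_binding(fit: Union[FitResult, SaturationCurve]) -> LigandBindingReport:
    """Map a fit to ligand-binding constants (K_d = (A_b)_sat / kappa0)."""
    c = _curve_of(fit)
    k_d = c.y_sat / c.kappa0
    return LigandBindingReport(
        ab_sat=c.y_sat, kappa0=c.kappa0, k_d=k_d, k_bind=1.0 / k_d,
        x_unit=c.x_unit or "mol/L", y_unit=c.y_unit or "mol/L",
    )


def as_enzyme(
    fit: Union[FitResult, SaturationCurve], e_t: Optional[float] = None
) -> EnzymeReport:
    """Map a fit to Michaelis-Menten constants.

    K_m = P_sat/kappa0 always; k_cat and k_bind require the total enzyme
    concentration e_t.  Scaling both empirical constants by the same
    factor (doubling E_t) leaves K_m unchanged.
    """
    c = _curve_of(fit)
    if e_t is not None and e_t <= 0:
        raise DomainError(f"e_t must be > 0, got {e_t!r}")
    k_m = c.y_sat / c.kappa0
    k_cat = c.y_sat / e_t if e_t is not None else None
    k_bind = c.kappa0 / e_t if e_t is not None else None
    return EnzymeReport(p_sat=c.y_sat, kappa0=c.kappa0, k_m=k_m, e_t=e_t,
                        k_cat=k_cat, k_bind=k_bind,
                        x_unit=c.x_unit, y_unit=c.y_unit)


def as_monod(fit: Union[FitResult, SaturationCurve]) -> MonodReport:
    """Map a fit to Monod growth constants (K = R_sat/kappa0)."""
    c = _curve_of(fit)
    return MonodReport(r_sat=c.y_sat, kappa0=c.kappa0, k_half=c.K,
                       x_unit=c.x_unit or "g/L", y_unit=c.y_unit or "g/L/min")


def as_functional_response(
    fit: Union[FitResult, SaturationCurve]
) -> FunctionalResponseReport:
    """Map a fit to Holling type II constants (K = N_sat/kappa0)."""
    c = _curve_of(fit)
    return FunctionalResponseReport(
        n_sat=c.y_sat, kappa0=c.kappa0, k_half=c.K,
        x_unit=c.x_unit or "prey/area", y_unit=c.y_unit or "prey/time",
    )


# --------------------------------------------------------------------------
# Inhibition classification
# --------------------------------------------------------------------------

# Signature table: (p_sat trend, kappa0 trend, k_m trend) -> label, where
# trends are "u" (unchanged), "d" (decreased) and k_m trend may be "u",
# "up", "down" or None (don't care).  Exposed as data so the mapping can
# be inspected or amended.
INHIBITION_SIGNATURES: list = [
    {"p_sat": "u", "kappa0": "u", "k_m": None, "label": "no_inhibition"},
    {"p_sat": "u", "kappa0": "d", "k_m": None, "label": "competitive"},
    {"p_sat": "d", "kappa0": "u", "k_m": None, "label": "uncompetitive"},
    {"p_sat": "d", "kappa0": "d", "k_m": "u", "label": "pure_noncompetitive"},
    {"p_sat": "d", "kappa0": "d", "k_m": "up", "label": "predominantly_competitive"},
    {"p_sat": "d", "kappa0": "d", "k_m": "down", "label": "predominantly_uncompetitive"},
]

VERDICT_LABELS = (
    "competitive", "uncompetitive", "pure_noncompetitive",
    "predominantly_competitive", "predominantly_uncompetitive",
    "no_inhibition", "inconsistent",
)


@dataclass(frozen=True)
class InhibitionVerdict:
    """Classification of an inhibitor's effect from paired fits."""

    label: str
    kappa0_ratio: float  # inhibited / control
    psat_ratio: float    # inhibited / control
    km_ratio: float      # inhibited / control
    tolerance: float

    def to_dict(self) -> dict:
        return {"label": self.label, "kappa0_ratio": self.kappa0_ratio,
                "psat_ratio": self.psat_ratio, "km_ratio": self.km_ratio,
                "tolerance": self.tolerance}


def _trend(ratio: float, tol: float) -> str:
    if ratio > 1 + tol:
        return "up"
    if ratio < 1 - tol:
        return "d"
    return "u"


def classify_inhibition(
    control: Union[FitResult, SaturationCurve],
    inhibited: Union[FitResult, SaturationCurve],
    rel_tol: float = 0.02,
) -> InhibitionVerdict:
    """Classify the inhibition type from control and inhibited fits.

    An increase of either empirical constant beyond tolerance is not an
    admissible inhibitor effect and yields the verdict ``inconsistent``
    (a verdict, not an exception).  Every pair of positive ratios maps to
    exactly one label.
    """
    if rel_tol <= 0:
        raise DomainError("rel_tol must be > 0")
    c0, c1 = _curve_of(control), _curve_of(inhibited)
    r_k0 = c1.kappa0 / c0.kappa0
    r_ps = c1.y_sat / c0.y_sat
    r_km = c1.K / c0.K

    t_ps, t_k0 = _trend(r_ps, rel_tol), _trend(r_k0, rel_tol)
    if t_ps == "up" or t_k0 == "up":
        label = "inconsistent"
    else:
        km_trend = _trend(r_km, rel_tol)
        km_key = {"u": "u", "up": "up", "d": "down"}[km_trend]
        label = "inconsistent"
        for row in INHIBITION_SIGNATURES:
            if row["p_sat"] == t_ps and row["kappa0"] == t_k0 and (
                row["k_m"] is None or row["k_m"] == km_key
            ):
                label = row["label"]
                break
    return InhibitionVerdict(label=label, kappa0_ratio=r_k0, psat_ratio=r_ps,
                             km_ratio=r_km, tolerance=rel_tol)
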