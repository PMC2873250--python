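"""Seeded synthetic saturation data: designs and noise models.

The generator emulates the classical saturation experiment: choose a set
of strictly positive x values (concentrations, densities), read y off a
true hyperbolic curve, and perturb it with either additive Gaussian noise
(constant sigma) or proportional noise (constant coefficient of
variation).  Draws that land at y <= 0 are redrawn rather than clipped,
so no point mass accumulates at zero — a deliberate truncation of the
Gaussian model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import SaturationCurve
from .data import XYDataSet
from .exceptions import DomainError, GenerationError

__all__ = ["SimSpec", "make_design", "generate"]

DESIGNS = ("linear", "log", "geometric")
NOISE_MODELS = ("none", "additive_gaussian", "proportional")


@dataclass(frozen=True)
class SimSpec:
    """Specification of a synthetic saturation experiment.

    design
        "linear": arithmetic grid x_max*(1..n)/n;
        "log": constant-ratio grid spanning [x_min_multiple*K,
        x_max_multiple*K] (the default, concentrating points where the
        curvature informs both constants);
        "geometric": doubling grid x_max/2^(n-1), ..., x_max/2, x_max.
    noise_scale
        sigma for additive_gaussian (y-units), CV for proportional.
    """

    curve: SaturationCurve
    design: str = "log"
    n_points: int = 12
    x_max_multiple: float = 10.0
    x_min_multiple: float = 0.2
    noise_model: str = "none"
    noise_scale: float = 0.0
    n_replicates: int = 1
    seed: int = 0
    include_zero: bool = False

    def __post_init__(self):
        if self.design not in DESIGNS:
            raise DomainError(f"design must be one of {DESIGNS}")
        if self.noise_model not in NOISE_MODELS:
            raise DomainError(f"noise_model must be one of {NOISE_MODELS}")
        if self.n_points < 3:
            raise DomainError("n_points must be >= 3")
        if self.noise_scale < 0:
            raise DomainError("noise_scale must be >= 0")
        if self.x_max_multiple <= 0 or self.x_min_multiple <= 0:
            raise DomainError("x range multiples must be > 0")
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")


def make_design(spec: SimSpec) -> np.ndarray:
    """The x grid of a SimSpec: n_points values in (0, x_max_multiple*K].

    x = 0 is appended only when include_zero is set.
    """
    k = spec.curve.K
    x_max = spec.x_max_multiple * k
    n = spec.n_points
    if spec.design == "linear":
        grid = x_max * np.arange(1, n + 1) / n
    elif spec.design == "log":
        grid = np.geomspace(spec.x_min_multiple * k, x_max, n)
    else:  # geometric: doubling grid anchored at x_max
        grid = x_max / 2.0 ** np.arange(n - 1, -1, -1)
    if spec.include_zero:
        grid = np.concatenate([[0.0], grid])
    return grid


def generate(spec: SimSpec) -> XYDataSet:
    """Draw a synthetic XYDataSet from a SimSpec; identical seeds give
    identical data.

    Non-positive draws are redrawn up to 100 times per value before the
    generator gives up (pathological noise scales).
    """
    rng = np.random.default_rng(spec.seed)
    x_grid = make_design(spec)
    x = np.repeat(x_grid, spec.n_replicates)
    reps = (np.tile(np.arange(spec.n_replicates), x_grid.size)
            if spec.n_replicates > 1 else None)
    y_true = spec.curve.eval(x)

    if spec.noise_model == "none" or spec.noise_scale == 0.0:
        y = y_true.copy()
    else:
        y = np.empty_like(y_true)
        for i, mu in enumerate(y_true):
            for _ in range(100):
                eps = rng.standard_normal()
                val = (mu + spec.noise_scale * eps
                       if spec.noise_model == "additive_gaussian"
                       else mu * (1.0 + spec.noise_scale * eps))
                if val > 0 or (x[i] == 0 and val == 0):
                    y[i] = val
                    break
            else:
                raise GenerationError(
                    f"could not draw a positive y at x={x[i]!r} after 100 "
                    f"attempts (noise_scale={spec.noise_scale})"
                )
        # the origin is noiseless by construction: y(0) = 0 exactly
        y[x == 0] = 0.0

    return XYDataSet(
        x=x, y=y,
        x_unit=spec.curve.x_unit, y_unit=spec.curve.y_unit,
        replicate_ids=reps,
        source=(f"simulated: kappa0={spec.curve.kappa0}, "
                f"y_sat={spec.curve.y_sat}, design={spec.design}, "
                f"noise={spec.noise_model}({spec.noise_scale}), "
                f"seed={spec.seed}"),
    )
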