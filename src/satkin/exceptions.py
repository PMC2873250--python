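"""Exception hierarchy for satkin.

The CLI maps these onto its exit-code contract: ``InputError`` (and its
subclasses) exit 2, ``FitFailureError`` exits 3.
"""


class SatkinError(Exception):
    """Base class for all satkin errors."""


class DomainError(SatkinError, ValueError):
    """An argument lies outside the mathematical domain of an operation
    (negative x, non-positive parameter, dx <= 0, ...)."""


class InputError(SatkinError, ValueError):
    """User-supplied data is unusable: too few points, non-positive
    responses, ragged or non-numeric files."""


class ParseError(InputError):
    """A data file could not be parsed; message carries the line number."""


class FitFailureError(SatkinError, RuntimeError):
    """An estimator could not produce a valid curve (non-saturating data,
    optimizer non-convergence)."""


class IntegrationError(SatkinError, RuntimeError):
    """Numerical integration of the slope law failed or left the positive
    quadrant."""


class GenerationError(SatkinError, RuntimeError):
    """The synthetic-data generator could not draw admissible values."""
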