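"""Exception hierarchy.

Validation problems (bad schemas, unsupported charge classes, malformed
inputs) and numerical problems (non-convergence, failed fits) are kept on
separate branches so the CLI can map them to distinct exit codes.
"""


class BaselinetoxError(Exception):
    """Base class for all package errors."""


class ValidationError(BaselinetoxError):
    """Invalid input data or configuration (CLI exit code 2)."""


class DomainError(ValidationError):
    """A scalar input outside its mathematical domain (e.g. C <= 0)."""


class UnsupportedChargeClassError(ValidationError):
    """No partition regression / baseline model exists for this charge class."""


class InsufficientDataError(ValidationError):
    """Too few data points for the requested fit."""


class DegenerateInputError(ValidationError):
    """Structurally valid input with no usable information (zero variance,
    zero sorptive volume, ...)."""


class MissingDescriptorError(ValidationError):
    """A chemical lacks the descriptor required by the requested model."""


class NumericalError(BaselinetoxError):
    """Numerical failure (CLI exit code 3)."""


class ConvergenceError(NumericalError):
    """Iterative solver did not converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: float | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


class FitError(NumericalError):
    """Nonlinear fit failed or the data cannot support one."""


class NoEffectError(NumericalError):
    """Concentration-response data show no positive trend; no EC derivable."""


class ExtrapolationWarning(UserWarning):
    """A regression was evaluated outside its stated validity range."""
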