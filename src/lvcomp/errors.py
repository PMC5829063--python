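"""Exception hierarchy for lvcomp.

All errors derive from :class:`LVCompError` so callers can catch the package's
failures with one clause.  Errors that signal bad user input additionally
derive from :class:`ValueError` to behave naturally in generic code.
"""


class LVCompError(Exception):
    """Base class for all lvcomp errors."""


class InvalidParameterError(LVCompError, ValueError):
    """A physical parameter is out of its admissible range."""


class InvalidInputError(LVCompError, ValueError):
    """A state or signal input violates its contract (e.g. negative calcium)."""


class InvalidStateError(LVCompError, ValueError):
    """A dynamic state is outside its admissible operating range."""


class InvalidGeometryError(LVCompError, ValueError):
    """Geometric quantities are non-physical (e.g. non-positive volumes)."""


class ShapeMismatchError(LVCompError, ValueError):
    """Two objects that must share a grid or discretization do not."""


class InsufficientDataError(LVCompError, ValueError):
    """Fewer data points than the operation requires."""


class ExtractionFailureError(LVCompError):
    """Echo dimension extraction produced non-physical averaged values."""


class GenerationFailureError(LVCompError):
    """Synthetic-data generation exhausted its retry budget."""


class EquilibriumFailureError(LVCompError):
    """The mechanical equilibrium solve did not converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class ConvergenceFailureError(LVCompError):
    """The cardiac-cycle limit cycle did not converge within the beat cap."""


class DegenerateFitError(LVCompError):
    """The Newton fit Jacobian is singular to working tolerance."""


class FitNonConvergenceError(LVCompError):
    """The Newton fit exceeded its iteration cap."""

    def __init__(self, message: str, residual_trace=None):
        super().__init__(message)
        self.residual_trace = list(residual_trace or [])


class SensitivityFailureError(LVCompError):
    """Both perturbed simulations of a sensitivity evaluation failed."""


class SchemaViolationError(LVCompError, ValueError):
    """A run configuration is missing or mistypes a required field."""
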