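"""Exception hierarchy.

Validation errors (bad inputs, bad configuration) are distinguished from
runtime failures (numerics, non-convergence) so the CLI can map them to
distinct exit codes.
"""


class SysmapError(Exception):
    """Base class for all package errors."""


class ValidationError(SysmapError):
    """Invalid user input: malformed files, bad parameters, schema problems."""


class InvalidDomainError(ValidationError):
    """Degenerate or inverted basis/state domain."""


class OutOfDomainError(SysmapError):
    """A value fell outside a basis domain beyond tolerance."""


class IntegrationError(SysmapError):
    """ODE solution became non-finite."""

    def __init__(self, message: str, time_reached: float | None = None):
        super().__init__(message)
        self.time_reached = time_reached


class SingularDesignError(SysmapError):
    """Rank-deficient regression design."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class TooShortError(ValidationError):
    """A trajectory has too few points to smooth."""


class NonConvergenceError(SysmapError):
    """Optimizer failed to converge; carries the best result found."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class ComponentCollapseError(SysmapError):
    """A mixture component's variance collapsed in every restart."""


class EmptyWindowError(ValidationError):
    """A clock-time selection produced no paired observations."""


class UnidentifiableBreakpointError(SysmapError):
    """No interior breakpoint improves on the single-segment fit."""


class ConfigRejectionError(ValidationError):
    """A simulation scenario would produce physically impossible data."""


class SchemaError(ValidationError):
    """An input table is missing required columns or contains duplicates."""


class InsufficientSpanError(ValidationError):
    """Fewer days of data than a check requires."""
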