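"""Exception hierarchy for the cprobit package.

All errors raised by the library derive from :class:`CprobitError`, so callers
(and the CLI) can catch a single base class.
"""


class CprobitError(Exception):
    """Base class for all cprobit errors."""


class SchemaError(CprobitError):
    """A required column is missing or a value cannot be parsed."""


class DataValidationError(CprobitError):
    """Input records violate the paired two-time-point design."""


class TieError(CprobitError):
    """A subject has identical outcomes at both time points (delta-y = 0)."""


class DesignError(CprobitError):
    """The difference design matrix is unusable (rank deficient, zero column, too few subjects)."""


class DomainError(CprobitError):
    """Argument outside the mathematical domain (e.g. Box-Cox on a non-positive outcome)."""


class ConvergenceError(CprobitError):
    """An iterative fit failed to converge."""


class InsufficientDataError(CprobitError):
    """Too few observations for the requested computation."""


class DegenerateSampleError(CprobitError):
    """A sample is constant (zero variance) where variability is required."""


class SimulationError(CprobitError):
    """The simulation configuration cannot produce valid data."""
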