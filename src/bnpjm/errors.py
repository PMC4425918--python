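"""Exception taxonomy used across the package.

All data-contract violations raise subclasses of :class:`CohortError` so that
callers can distinguish "your input is malformed" from numerical failures
(:class:`ConvergenceError`, :class:`NumericalError`).
"""


class CohortError(ValueError):
    """Base class for violations of the cohort data contract."""


class SchemaError(CohortError):
    """A required column is missing or has the wrong dtype."""


class LinkageError(CohortError):
    """Longitudinal and survival tables are inconsistent with each other."""


class ParseError(CohortError):
    """A cell could not be parsed as the expected numeric type."""


class DomainError(CohortError):
    """A value lies outside the mathematical domain of an operation."""


class DegenerateCovariateError(CohortError):
    """A covariate cannot be standardized (zero or undefined SD)."""


class ChronologyError(CohortError):
    """Measurements supplied out of time order."""


class DegenerateOutcomeError(CohortError):
    """An outcome has no observed events (or no cases/controls for ROC)."""


class SingularDesignError(CohortError):
    """The fixed-effects design matrix is rank deficient."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge within its iteration cap."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NumericalError(RuntimeError):
    """A numerical routine (root finder, quadrature) failed."""
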