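"""Exception hierarchy shared across the pipeline stages.

Every malformed input is rejected with an error naming the offending
file/row/rule; nothing is silently coerced or dropped.
"""

from __future__ import annotations


class SynerkitError(Exception):
    """Base class for all package errors."""


class SchemaError(SynerkitError):
    """A required column is missing from an input table."""


class ParseError(SynerkitError):
    """A cell could not be parsed; carries the 1-based file row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class DuplicateRecordError(SynerkitError):
    """The same (agent, dose, replicate, time) key appears twice."""


class UnitConsistencyError(SynerkitError):
    """A single agent carries more than one dose unit."""


class ValidationError(SynerkitError):
    """A value violates a domain invariant (dose <= 0, fa outside [0, 1], ...)."""


class MissingControlError(SynerkitError):
    """No uninhibited control trace is available for an agent batch."""


class UndefinedControlError(SynerkitError):
    """The control velocity is zero, so percent inhibition is undefined."""


class InsufficientDataError(SynerkitError):
    """Fewer usable points than the operation requires."""


class DegenerateDesignError(SynerkitError):
    """All doses identical (or otherwise rank-deficient design)."""


class DomainError(SynerkitError, ValueError):
    """An argument is outside the mathematical domain of the operation."""


class ConvergenceError(SynerkitError):
    """Nonlinear fit failed to converge; carries the best residual sum of squares."""

    def __init__(self, message: str, best_rss: float | None = None):
        super().__init__(message)
        self.best_rss = best_rss


class SolverError(SynerkitError):
    """Root bracketing failed; carries the bracket endpoints and values."""

    def __init__(self, message: str, bracket: tuple | None = None):
        super().__init__(message)
        self.bracket = bracket
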