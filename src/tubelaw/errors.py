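"""Exception and warning taxonomy shared across the package."""


class TubeLawError(Exception):
    """Base class for all package errors."""


class DomainError(TubeLawError, ValueError):
    """A parameter lies outside its physically admissible range."""


class SchemaError(TubeLawError, ValueError):
    """A file or config does not match the expected schema.

    Carries optional ``rows`` (offending 0-based row numbers) for tabular input.
    """

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class InsufficientDataError(TubeLawError):
    """Too few samples remain after preprocessing to attempt a fit."""


class EstimationError(TubeLawError):
    """Every candidate fit failed; carries per-candidate diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class IllConditionedParametersWarning(UserWarning):
    """Model parameters cancel to the printed precision; the prediction is
    numerically meaningless and should not be trusted."""


class ShuffledDataWarning(UserWarning):
    """Input rows were not time-ordered and have been sorted on ingestion."""
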