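"""Exception hierarchy shared across the package."""


class ClicalError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ClicalError, ValueError):
    """An argument is outside the mathematical/clinical domain of an operation."""


class SchemaError(ClicalError):
    """A cohort file is missing a required column or has an unusable header."""


class CohortFormatError(ClicalError):
    """A data row cannot be parsed (malformed numeric, duplicate id, ...)."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class IntentClassificationError(ClicalError):
    """Treatment intent cannot be determined (missing dose data on a lesion)."""


class MissingDataError(ClicalError):
    """A patient lacks a value required for scoring; signals exclusion, never a default."""

    def __init__(self, message: str, variables: tuple[str, ...] = ()):
        super().__init__(message)
        self.variables = variables


class SearchError(ClicalError):
    """No feasible cut-point candidate exists under the search constraints."""


class ConfigError(ClicalError):
    """An invalid simulation or pipeline configuration value."""

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class PipelineError(ClicalError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
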