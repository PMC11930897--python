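"""Exception hierarchy shared across the package."""


class ClungradsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ClungradsError, ValueError):
    """A domain object violates an invariant (bad diameter, unknown GVR, ...)."""


class SchemaError(ValidationError):
    """A tabular input is missing required columns or has an unusable layout."""

    def __init__(self, message: str, missing: list[str] | None = None):
        super().__init__(message)
        self.missing = list(missing or [])


class RowError(ValidationError):
    """A specific input row could not be parsed; carries the row index."""

    def __init__(self, message: str, row: int):
        super().__init__(f"row {row}: {message}")
        self.row = row


class ContractError(ClungradsError, ValueError):
    """An operation was called outside its contract (e.g. unreachable category)."""


class CalibrationError(ClungradsError, ValueError):
    """Requested confusion-cell targets are infeasible under the configuration."""


class DegenerateInputError(ClungradsError, ValueError):
    """Statistically degenerate input (single-class labels, constant scores)."""
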