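"""Exception hierarchy shared across the package."""


class PinfishError(Exception):
    """Base class for all package errors."""


class SchemaError(PinfishError):
    """A tabular input does not match the documented column schema."""


class ValidationError(PinfishError):
    """A record violates a domain invariant; carries the offending row."""

    def __init__(self, message, row=None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class InsufficientDataError(PinfishError):
    """Too few observations to perform the requested computation."""


class DegenerateSeriesError(PinfishError):
    """A series has no variance (or an undefined mean) where spread is required."""


class ConvergenceError(PinfishError):
    """An iterative fit failed to converge (e.g. perfect separation)."""
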