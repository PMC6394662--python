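"""Exception hierarchy shared across the package."""


class ColonyKitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ColonyKitError, ValueError):
    """A parameter or value violates a documented precondition."""


class InputError(ColonyKitError, IOError):
    """An input file is missing, unreadable or malformed at the container level."""


class ParseError(ValidationError):
    """A text file failed to parse; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class InsufficientDataError(ValidationError):
    """Not enough data points/bins for the requested fit."""


class GenerationError(ColonyKitError):
    """Synthetic plate generation could not satisfy the requested geometry."""
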