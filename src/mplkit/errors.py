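"""Exception hierarchy shared across the toolkit."""


class MplkitError(Exception):
    """Base class for all toolkit errors."""


class InvalidInputError(MplkitError, ValueError):
    """Input data violates an operation's precondition."""


class InvalidParameterError(MplkitError, ValueError):
    """A parameter is outside its documented domain."""


class FormatError(MplkitError, ValueError):
    """A file could not be parsed; carries a line number where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InsufficientSamplesError(InvalidInputError):
    """Too few non-missing values to make a statistical call."""


class UndefinedCorrelationError(MplkitError, ValueError):
    """Correlation undefined because one score vector has zero variance."""
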