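"""Exception hierarchy shared across the package."""


class BicistronError(Exception):
    """Base class for all package-specific errors."""


class ParseError(BicistronError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(BicistronError, ValueError):
    """An in-memory record violates a domain invariant."""


class UndefinedStatisticError(BicistronError, ValueError):
    """A statistic is undefined for the given input (e.g. 0/0 rate, TE at
    zero mRNA, constant-input correlation, saturated K2P distance)."""
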