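"""Exception hierarchy shared across the package."""


class MethTriageError(Exception):
    """Base class for all package errors."""


class ParseError(MethTriageError, ValueError):
    """A file could not be parsed; message names the path and line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        if path is not None and line is not None:
            message = f"{path}:{line}: {message}"
        elif path is not None:
            message = f"{path}: {message}"
        super().__init__(message)
        self.path = path
        self.line = line


class ValidationError(MethTriageError, ValueError):
    """Input violated a documented invariant (domain, uniqueness, pairing...)."""


class InsufficientDataError(MethTriageError, ValueError):
    """Too few observations for the requested statistic (e.g. < 2 pairs)."""
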