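"""Exception types shared across the package."""


class TLPCensusError(Exception):
    """Base class for all package errors."""


class ParseError(TLPCensusError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
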