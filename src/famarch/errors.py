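"""Exception types shared across the package."""


class FamarchError(Exception):
    """Base class for all package errors."""


class ValidationError(FamarchError, ValueError):
    """An input violates a documented invariant (bad argument, inconsistent ids)."""


class ParseError(FamarchError, ValueError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
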