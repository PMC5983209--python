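"""Exception types shared across the package."""


class TrapscreenError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TrapscreenError):
    """A file could not be parsed in its declared dialect.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ValidationError(TrapscreenError):
    """Input data violated a semantic invariant (bad strand, duplicate id, ...)."""
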