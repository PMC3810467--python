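"""Exception hierarchy shared across the package."""


class MemscaleError(Exception):
    """Base class for all package errors."""


class ValidationError(MemscaleError, ValueError):
    """A precondition on an operation's inputs was violated."""


class ConfigError(MemscaleError, ValueError):
    """An invalid configuration (missing path, bad counts, bad weights)."""


class ParseError(MemscaleError, ValueError):
    """A file could not be parsed; carries path and 1-based line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class EmptyCorpusError(MemscaleError, ValueError):
    """An n-gram stream contained no records."""


class UnknownWordError(MemscaleError, KeyError):
    """A word was looked up that is not present in the semantic space."""

    def __init__(self, word: str):
        super().__init__(word)
        self.word = word

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"word not present in the semantic space: {self.word!r}"


class SynonymTestError(MemscaleError, ValueError):
    """No usable synonym pair survived vocabulary filtering."""


class DegenerateGeometryError(MemscaleError, ValueError):
    """Collinear triangle vertices or another degenerate 2-D configuration."""
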