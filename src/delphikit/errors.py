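"""Exception hierarchy.

All errors raised on bad *data* derive from :class:`DelphiError`, so callers
(and the CLI) can distinguish validation failures from genuine I/O failures,
which surface as the builtin :class:`OSError`.
"""


class DelphiError(Exception):
    """Base class for all validation and domain errors."""


class ParseError(DelphiError):
    """A file could not be parsed; carries the offending path/line."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class SchemaError(DelphiError):
    """Structurally valid file with semantically invalid content."""


class DomainError(DelphiError):
    """An argument is outside its documented domain."""


class EmptyScoreError(DelphiError):
    """An item has no evaluable score; it must be flagged, never scored."""


class LedgerError(DelphiError):
    """A decision ledger is inconsistent with the questionnaire version."""
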