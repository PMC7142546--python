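"""Exception hierarchy.

All user-facing errors raised by the library derive from
:class:`IsomirkitError` so that callers (and the CLI) can distinguish
validation problems from genuine bugs.
"""


class IsomirkitError(Exception):
    """Base class for all isomirkit errors."""


class ValidationError(IsomirkitError, ValueError):
    """Input data violates a documented invariant (bad coordinates,
    duplicate identifiers, malformed probability vectors, ...)."""


class FormatError(ValidationError):
    """A file could not be parsed as the expected format; carries the
    offending record index where known."""

    def __init__(self, message: str, record_index: int | None = None):
        super().__init__(message)
        self.record_index = record_index
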