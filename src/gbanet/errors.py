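"""Exception hierarchy.

User-facing errors (bad inputs, bad parameters) derive from :class:`UserError`
and map to CLI exit code 1; anything else is an internal error (exit code 2).
"""


class GbanetError(Exception):
    """Base class for all package errors."""


class UserError(GbanetError):
    """The user supplied something unusable; fixable by the caller."""


class ParseError(UserError):
    """A file could not be parsed; the message names the offending line."""


class ParameterError(UserError):
    """A parameter is outside its valid range."""


class EmptyInputError(UserError):
    """An input collapsed to nothing after cleaning/intersection."""


class FingerprintMismatchError(GbanetError):
    """Feature/model/corpus settings do not match; guards against scoring
    a model on features built under different parameters."""
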