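"""Exception hierarchy shared across the package."""


class MVIntegrateError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MVIntegrateError):
    """A delimited table could not be parsed as numeric data."""


class AlignmentError(MVIntegrateError):
    """Sample identifiers across views could not be reconciled."""


class ValidationError(MVIntegrateError, ValueError):
    """An input violates a documented precondition or invariant."""


class ModelIOError(MVIntegrateError):
    """A serialized model file is unreadable, truncated or incompatible."""


class NoSelectionError(MVIntegrateError):
    """Sparsification removed every coordinate (tuning value too large)."""
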