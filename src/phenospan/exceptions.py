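"""Exception hierarchy shared across the package."""


class PhenospanError(Exception):
    """Base class for all package errors."""


class FormatError(PhenospanError, ValueError):
    """A serialized input (annotation row, span field, dictionary row) is malformed."""


class ValidationError(PhenospanError, ValueError):
    """An in-memory object violates a structural invariant."""


class GenerationError(PhenospanError, RuntimeError):
    """The synthetic generator cannot realize the requested configuration."""
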