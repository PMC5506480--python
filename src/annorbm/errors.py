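"""Exception types shared across the package."""


class AnnorbmError(Exception):
    """Base class for package errors."""


class ValidationError(AnnorbmError):
    """An input violated a documented precondition or invariant."""


class ParseError(AnnorbmError):
    """A flat file could not be parsed."""


class GenerationError(AnnorbmError):
    """The synthetic generator could not satisfy its constraints."""
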