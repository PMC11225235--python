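"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input violates a documented precondition."""


class ParseError(ValidationError):
    """A file could not be parsed; the message carries the offending line number."""


class InsufficientOverlapError(ValidationError):
    """Too few clusters are jointly covered by the sample and the atlas."""
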