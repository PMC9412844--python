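"""Exception hierarchy shared across the package."""


class KcmError(Exception):
    """Base class for all kcmnet errors."""


class ValidationError(KcmError):
    """Input violates a structural invariant (duplicate ids, shape mismatch...)."""


class ParseError(KcmError):
    """A delimited-text file could not be parsed into a numeric table."""
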