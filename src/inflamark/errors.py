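"""Exception types shared across the package."""


class InflamarkError(Exception):
    """Base class for all package-specific errors."""


class ParseError(InflamarkError, ValueError):
    """A file could not be parsed; the message names the offending line/row."""


class ValidationError(InflamarkError, ValueError):
    """Parsed content violates a structural invariant (duplicates, cycles, ...)."""


class ConstantInputError(InflamarkError, ValueError):
    """A correlation was requested on a constant vector; the result is undefined."""
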