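"""Exception hierarchy shared across the package."""


class EndemisError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EndemisError, ValueError):
    """Input data violates a documented invariant."""


class ParseError(EndemisError, ValueError):
    """A file or string could not be parsed."""


class FormatError(EndemisError, ValueError):
    """An identifier or file is not in the expected format."""


class AlignmentError(EndemisError, ValueError):
    """Two objects that must share a label set do not."""


class ConfigurationError(EndemisError, ValueError):
    """Parameter values are inconsistent or out of range."""


class DomainError(EndemisError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""
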