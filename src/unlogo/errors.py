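"""Exception hierarchy shared across the package."""


class LogoError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(LogoError, ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(LogoError):
    """Unsupported or malformed image file format."""


class AlphaChannelError(FormatError):
    """PNG input carries a transparency channel, which is not supported."""


class ParseError(LogoError):
    """A motif text file could not be parsed."""


class BlankImageError(LogoError):
    """The image (or requested region) contains no logo content."""


class InfeasibleError(LogoError):
    """No solution exists for the requested entropy-inversion instance."""


class UndefinedCorrelationError(LogoError):
    """Pearson correlation is undefined (zero variance, unequal matrices)."""
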