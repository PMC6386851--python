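"""Exception hierarchy.

All library errors derive from :class:`FetalicaError` so callers can catch
one base class. Value-level misuse additionally derives from the matching
builtin (``ValueError``) so generic handling keeps working.
"""


class FetalicaError(Exception):
    """Base class for all errors raised by this package."""


class InvalidArgumentError(FetalicaError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(FetalicaError, ValueError):
    """Input data is degenerate (constant channel, rank-deficient covariance ...)."""


class NotWhitenedError(FetalicaError, ValueError):
    """Data handed to the ICA fixed-point iteration is not whitened."""


class SelectionError(FetalicaError, RuntimeError):
    """Fetal-channel selection is impossible (all candidate sources degenerate)."""


class ProtocolError(FetalicaError, ValueError):
    """Base class for data-package codec errors."""


class PackageLengthError(ProtocolError):
    """A raw data package does not have the expected byte length."""


class PackageMagicError(ProtocolError):
    """A raw data package does not start with the expected magic bytes."""


class PackageCRCError(ProtocolError):
    """A raw data package fails its CRC-16 integrity check."""
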