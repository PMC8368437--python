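"""Exception hierarchy for the ictalmeg package."""


class IctalMegError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IctalMegError, ValueError):
    """Invalid parameter or configuration value."""


class GeometryError(IctalMegError, ValueError):
    """Source/sensor geometry violates the conductor model."""


class EmptyDataError(IctalMegError, ValueError):
    """An operation was left with no usable data."""


class NumericalError(IctalMegError, ArithmeticError):
    """A numerical step failed (e.g. singular covariance)."""


class NoSourceError(IctalMegError, ValueError):
    """A source map contains no activity to localize."""


class FormatError(IctalMegError, ValueError):
    """A file does not conform to the documented container layout."""


class ValidationError(IctalMegError, ValueError):
    """A record is missing required fields or violates an invariant."""
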