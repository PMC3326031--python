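"""Exception hierarchy shared across the package."""


class SnprankError(Exception):
    """Base class for all package errors."""


class DomainError(SnprankError, ValueError):
    """A value falls outside the domain an operation is defined on."""


class FormatError(SnprankError, ValueError):
    """A table or alignment file violates the expected format."""


class InsufficientDataError(SnprankError, ValueError):
    """Too few observations to compute a statistic."""


class UndefinedCorrelationError(SnprankError, ValueError):
    """Correlation is undefined (a coordinate is constant)."""


class UnrankableError(SnprankError, ValueError):
    """No predictor call is available, so no consensus rank exists."""


class ConfigError(SnprankError, ValueError):
    """Invalid simulation or pipeline configuration."""
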