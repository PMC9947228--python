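"""Exception hierarchy shared across the package."""


class BiclinkError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BiclinkError, ValueError):
    """Invalid configuration value or combination."""


class DomainError(BiclinkError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class UndefinedStatisticError(BiclinkError, ValueError):
    """A statistic is undefined for the given data (e.g. all-missing column)."""


class AlignmentError(BiclinkError, ValueError):
    """Participant identifiers of two tables cannot be aligned."""


class LookupError_(BiclinkError, KeyError):
    """An identifier was not found where it is required."""


class EmptyResultError(BiclinkError, RuntimeError):
    """An operation removed or filtered everything away."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report
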