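"""Exception hierarchy shared across the package."""


class CftriageError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CftriageError):
    """A configuration value violates its contract."""


class DomainError(CftriageError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class DegenerateInputError(CftriageError, ValueError):
    """Input is structurally valid but carries no usable signal (e.g. all-zero coverage)."""


class ComputationError(CftriageError):
    """A derived statistic is undefined for this input (e.g. zero panel SD)."""


class SchemaError(CftriageError, ValueError):
    """A table does not conform to its declared schema."""


class InputError(CftriageError, ValueError):
    """Mismatched or inconsistent inputs to a multi-input operation."""
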