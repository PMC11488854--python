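"""Exception types shared across the package."""


class NeuroagingError(Exception):
    """Base class for package errors."""


class ConfigurationError(NeuroagingError, ValueError):
    """Invalid generator or model configuration."""


class SchemaError(NeuroagingError, ValueError):
    """Input table is missing mandatory columns or has malformed rows."""


class IntegrityError(NeuroagingError, ValueError):
    """Input table violates uniqueness or range constraints."""


class ConvergenceError(NeuroagingError, RuntimeError):
    """Model fit failed to converge; carries diagnostic context."""


class DegenerateInputError(NeuroagingError, ValueError):
    """Input has no usable variation (zero variance, constant map, ...)."""
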