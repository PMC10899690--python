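"""Exception hierarchy shared across the pipeline."""


class SomnoriskError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SomnoriskError, ValueError):
    """Invalid configuration value (bad probability, non-positive count, ...)."""


class DataError(SomnoriskError, ValueError):
    """Malformed input data (overlapping intervals, negative durations, ...)."""


class ValidationError(SomnoriskError, ValueError):
    """Value outside its documented domain (ISI item out of [0, 4], ...)."""


class SchemaError(ValidationError):
    """Tabular file does not match its declared schema."""
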