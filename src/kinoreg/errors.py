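"""Exception types shared across the package."""


class KinoregError(Exception):
    """Base class for package errors."""


class ValidationError(KinoregError, ValueError):
    """Raised when input data violate a documented contract."""


class ConfigurationError(KinoregError, ValueError):
    """Raised when a configuration object is internally inconsistent."""


class SchemaError(ValidationError):
    """Raised when a feature matrix does not match the expected schema."""
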