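"""Exception hierarchy shared across the pipeline stages."""


class BodyCompError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BodyCompError):
    """Invalid generator or pipeline configuration (bad SDs, n too small, ...)."""


class DomainError(BodyCompError):
    """An input value lies outside the physically meaningful domain."""


class InsufficientDataError(BodyCompError):
    """Too few observations for the requested computation."""


class MissingFieldError(BodyCompError):
    """A required per-subject field (body volume, dilution space, ...) is absent."""


class SchemaError(BodyCompError):
    """A tabular input does not match the expected column schema."""
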