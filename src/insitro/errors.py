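"""Exception types shared across the pipeline."""


class InsitroError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(InsitroError, ValueError):
    """An invalid generator or pipeline configuration; names the offending field."""


class ValidationError(InsitroError, ValueError):
    """A table failed schema or content validation."""


class DomainError(InsitroError, ValueError):
    """A value outside the mathematical domain of an operation."""
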