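"""Exception hierarchy shared across the pipeline."""


class AquariskError(Exception):
    """Base class for all package errors."""


class DomainError(AquariskError):
    """Input data outside the model's domain (negative concentration, empty table)."""


class ParameterError(AquariskError):
    """Invalid exposure, toxicity or generator parameter."""


class ConfigurationError(AquariskError):
    """Inconsistent configuration: missing toxicity entries, unknown metals, bad pipeline settings."""


class ParseError(AquariskError):
    """Structured CSV/config parse failure; message carries row numbers where known."""
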