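"""Exception hierarchy shared across the package."""


class MirmintError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MirmintError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class InputError(MirmintError, ValueError):
    """Invalid input data (schema, domain, or consistency violation)."""


class SchemaError(InputError):
    """Malformed file content; carries file path and, when known, line number."""

    def __init__(self, message: str, path=None, line=None):
        detail = message
        if path is not None:
            detail = f"{path}: {detail}"
        if line is not None:
            detail = f"{detail} (line {line})"
        super().__init__(detail)
        self.path = path
        self.line = line


class NoExponentialPhaseError(InputError):
    """Amplification curve has no usable exponential (log-linear) phase."""
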