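"""Exception types shared across the package."""


class SmmiraError(Exception):
    """Base class for all package errors."""


class ValidationError(SmmiraError, ValueError):
    """Raised when inputs violate a documented precondition."""


class FormatError(SmmiraError, ValueError):
    """Raised when an input file cannot be parsed."""


class ConfigError(SmmiraError, ValueError):
    """Raised when a configuration value is inconsistent."""
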