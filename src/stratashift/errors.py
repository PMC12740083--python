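"""Exception types shared across the package."""


class StratashiftError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StratashiftError, ValueError):
    """Raised when a file or run configuration is malformed (e.g. missing columns)."""


class InputError(StratashiftError, ValueError):
    """Raised when an input is structurally valid but unusable (e.g. zero rows)."""


class DomainError(StratashiftError, ValueError):
    """Raised when a numeric argument is outside the mathematical domain."""
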