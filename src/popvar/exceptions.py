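"""Exception types shared across the package."""


class PopvarError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PopvarError, ValueError):
    """An invalid simulation or analysis configuration."""


class DataError(PopvarError, ValueError):
    """Malformed, degenerate or inconsistent input data."""
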