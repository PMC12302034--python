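"""Exception hierarchy used across the package."""


class OFMLError(Exception):
    """Base class for package errors."""


class ConfigurationError(OFMLError, ValueError):
    """An invalid setting (bad hyper-parameter, inconsistent variant, ...)."""


class DataError(OFMLError, ValueError):
    """Malformed or degenerate input data."""


class DivergenceError(OFMLError, RuntimeError):
    """Training produced a non-finite loss; names the first bad component."""
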