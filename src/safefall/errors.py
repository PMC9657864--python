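"""Exception hierarchy shared across the package."""


class SafefallError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SafefallError):
    """A file does not conform to the documented dialect (e.g. missing column)."""


class DataError(SafefallError):
    """Input data violate a contract (non-monotone time, shape mismatch, ...)."""


class ConfigurationError(SafefallError):
    """A configuration value is invalid or inconsistent."""
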