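"""Exception types shared across the package."""


class VLSMError(ValueError):
    """Base class for all package errors."""


class GridMismatchError(VLSMError):
    """A volume does not live on the analysis template grid."""


class ValidationError(VLSMError):
    """An input violates a data-contract invariant."""


class ConfigError(VLSMError):
    """A configuration value is out of its admissible range."""


class InsufficientDataError(VLSMError):
    """A statistic cannot be computed from the data provided (e.g. group too small)."""
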