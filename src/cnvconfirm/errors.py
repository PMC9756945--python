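"""Exception hierarchy shared across the package."""


class CnvConfirmError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CnvConfirmError):
    """An input value violates a documented precondition."""


class OrderingError(ValidationError):
    """Input that must be sorted / strictly increasing is not."""


class MissingDataError(CnvConfirmError):
    """A required record (target, sample, file entry) is absent."""


class DegenerateSampleError(CnvConfirmError):
    """A sample's depth profile carries no usable signal (e.g. all zeros)."""


class ConfigurationError(CnvConfirmError):
    """An unknown or inconsistent configuration value."""
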