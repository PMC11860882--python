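"""Exception hierarchy shared across the package."""


class CarescapeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CarescapeError):
    """A study or pipeline configuration violates its invariants."""


class ValidationError(CarescapeError):
    """Input data fails a structural or range check."""


class ComputationError(CarescapeError):
    """A statistic is undefined or a fit failed on the given data."""
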