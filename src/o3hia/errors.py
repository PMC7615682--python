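"""Exception hierarchy for the ozone health-impact pipeline.

Validation problems (bad configuration, malformed files) and runtime
problems (misaligned inputs, failed fits) are kept on separate branches so
the command-line interface can map them to distinct exit codes.
"""


class O3HIAError(Exception):
    """Base class for all package errors."""


class ValidationError(O3HIAError):
    """Invalid configuration or malformed input data."""


class ConfigError(ValidationError):
    """Inconsistent or out-of-range configuration values."""


class DataFormatError(ValidationError):
    """A file or in-memory table violates the expected schema."""


class AlignmentError(O3HIAError):
    """Two inputs that must share city/date coverage do not."""


class CityLookupError(O3HIAError):
    """A city cannot be resolved to a grid cell or lookup row."""


class FittingError(O3HIAError):
    """A bias map cannot be fitted (e.g. too few paired days in a month)."""


class BiasApplicationError(O3HIAError):
    """A bias map is applied to data it was not fitted for."""


class ComputationError(O3HIAError):
    """A downstream computation received degenerate input (empty series,
    zero denominator, ...)."""
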