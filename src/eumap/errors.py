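"""Exception types shared across the pipeline stages."""


class EumapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EumapError):
    """A generator or stage was configured inconsistently."""


class SchemaError(EumapError):
    """Feature/band/label schemas do not line up between producer and consumer."""


class SpacingError(ConfigurationError):
    """Requested sample count is infeasible at the requested minimum spacing."""


class DegenerateInputError(EumapError):
    """Input is degenerate for the requested statistic (zero variance, constant raster...)."""


class UndefinedMetricError(EumapError):
    """A metric is undefined for this input (empty margin, chance agreement = 1...)."""
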