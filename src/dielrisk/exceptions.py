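"""Exception types shared across the package."""


class DielRiskError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(DielRiskError, ValueError):
    """A parameter is outside its documented range."""


class InsufficientDataError(DielRiskError, ValueError):
    """Too few observations to carry out the requested estimate."""


class EmptySelectionError(DielRiskError, ValueError):
    """A filter matched no records."""


class EmptyCohortError(DielRiskError, ValueError):
    """A stratum filter matched no monitored animals."""


class UndefinedWeightsError(DielRiskError, ValueError):
    """All identified-cause cumulative incidences are zero."""


class ConfigError(DielRiskError, ValueError):
    """An analysis configuration is invalid or incomplete."""


class DataError(DielRiskError, ValueError):
    """An input table violates its schema or invariants."""
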