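"""Exception and warning types shared across the package."""


class MfcFluxError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MfcFluxError, ValueError):
    """An input lies outside the physical domain of an operation."""


class FormulaError(MfcFluxError, ValueError):
    """A chemical species string could not be parsed."""


class ConfigurationError(MfcFluxError, ValueError):
    """A reaction or configuration object is missing a required piece."""


class InconsistentDataError(MfcFluxError, ValueError):
    """Measured quantities contradict each other (e.g. more nitrite than nitrate lost)."""


class InsufficientDataError(MfcFluxError, ValueError):
    """Too few samples to perform the requested computation."""


class DegenerateDataError(MfcFluxError, ValueError):
    """Data carry no usable signal (e.g. an all-zero concentration series)."""


class ParameterError(MfcFluxError, ValueError):
    """An analysis parameter is invalid for the given data (e.g. smoothing window too long)."""


class SchemaError(MfcFluxError, ValueError):
    """An input table does not match the documented CSV dialect."""


class InfeasibleConfigError(MfcFluxError, ValueError):
    """A simulation configuration cannot produce a physically sensible cycle."""


class NoInputError(MfcFluxError, FileNotFoundError):
    """A pipeline run found nothing to analyze."""


class ConservationWarning(UserWarning):
    """Electron bookkeeping closed with a negative residual (measurement inconsistency)."""


class DataQualityWarning(UserWarning):
    """A measured series violates an expectation (COD increase, residual ammonium, ...)."""


class StageWarning(UserWarning):
    """A batch-cycle stage could not be located in the voltage trace."""
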