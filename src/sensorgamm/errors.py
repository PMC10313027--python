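"""Exception hierarchy for sensorgamm.

All package errors derive from :class:`SensorGammError` so callers can catch
one base class; the subclasses mirror the distinct failure contracts of the
pipeline stages.
"""


class SensorGammError(Exception):
    """Base class for all sensorgamm errors."""


class ConfigurationError(SensorGammError):
    """A dialect / config file is missing required keys or columns."""


class EmptyInputError(SensorGammError):
    """An input table or record collection contained no usable data."""


class DataValidityError(SensorGammError):
    """Input values violate a physical or contractual constraint."""


class IdentifiabilityError(SensorGammError):
    """Too few complete rows to identify a regression."""


class DegenerateCovariateError(SensorGammError):
    """A covariate has too little spread to support a spline basis."""


class CollinearityError(SensorGammError):
    """The joint smooth design is singular; covariates are collinear."""


class DomainError(SensorGammError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class NonStationaryError(DomainError):
    """ARMA parameters violate stationarity or invertibility."""


class SelectionError(SensorGammError):
    """Every candidate model in a selection grid failed to fit."""


class SimulationSpecError(SensorGammError):
    """A synthetic-data spec is internally inconsistent."""
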