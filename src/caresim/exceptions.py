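"""Exception hierarchy.

Everything raised on purpose derives from :class:`CaresimError` so callers can
catch the package's own failures without swallowing programming errors.
"""


class CaresimError(Exception):
    """Base class for all errors raised by caresim."""


class InputDomainError(CaresimError, ValueError):
    """A scalar input lies outside its mathematical domain."""


class UnclassifiableError(CaresimError):
    """Care-need items are too incomplete to assign a dependency level."""


class ConfigurationError(CaresimError):
    """A configuration object or file is invalid or inconsistent."""


class EstimationError(CaresimError):
    """A transition model could not be estimated (zero events, separation...)."""


class CovariateError(CaresimError, KeyError):
    """A model covariate cannot be computed from the individual state."""


class RakingError(CaresimError):
    """Iterative proportional fitting cannot match the requested margins."""


class ReportingError(CaresimError):
    """Run results lack something the reporting layer needs."""
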