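"""Exception hierarchy shared across the package."""


class LE8SurvError(Exception):
    """Base class for all package errors."""


class ValidationError(LE8SurvError, ValueError):
    """Raised when an input value is missing, malformed, or out of the
    physiologic / admissible range.  The message names the offending field."""


class ParameterError(LE8SurvError, ValueError):
    """Raised when a specification object (cohort spec, scenario, model
    spec) carries an inadmissible parameter."""


class DataConsistencyError(LE8SurvError, ValueError):
    """Raised when linked records contradict each other, e.g. an event
    recorded after the censoring date."""


class DesignMatrixError(LE8SurvError, ValueError):
    """Raised for rank-deficient or constant-column design matrices."""


class ConvergenceError(LE8SurvError, RuntimeError):
    """Raised when a likelihood maximisation diverges (e.g. monotone
    likelihood under complete separation)."""


class EstimationError(LE8SurvError, ValueError):
    """Raised when an estimator is undefined for the supplied data
    (no events, zero person-years, ...)."""
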