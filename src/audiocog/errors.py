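"""Exception hierarchy for audiocog.

All package-specific failures derive from :class:`AudiocogError` so callers can
catch one base class; subclasses also derive from the closest builtin
(ValueError / RuntimeError) for idiomatic handling.
"""


class AudiocogError(Exception):
    """Base class for all audiocog errors."""


class InvalidParameterError(AudiocogError, ValueError):
    """A model or config parameter is outside its valid domain."""


class ValidationError(AudiocogError, ValueError):
    """Input data (table, config, response vector) failed validation."""


class InsufficientDataError(AudiocogError, ValueError):
    """Too few observations to compute the requested statistic."""


class DegenerateSampleError(AudiocogError, ValueError):
    """A sample with zero spread where a scale estimate is required."""


class ThresholdUndefinedError(AudiocogError, RuntimeError):
    """A staircase did not converge, so no threshold is defined."""


class StandardizationError(AudiocogError, ValueError):
    """A column could not be z-scored (zero variance)."""


class CalibrationError(AudiocogError, ValueError):
    """The requested measure calibration is infeasible for the task engines."""
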