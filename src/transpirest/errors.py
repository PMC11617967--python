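"""Exception and warning hierarchy.

All domain failures derive from :class:`TranspirestError` so callers can
catch the package's errors without also swallowing programming mistakes.
"""


class TranspirestError(ValueError):
    """Base class for all domain errors raised by this package."""


class TemperatureRangeError(TranspirestError):
    """Temperature outside the validity window of the saturation-pressure fit."""


class PsychroDomainError(TranspirestError):
    """Physically inadmissible psychrometric input (e.g. rH outside 0-100 %)."""


class SupersaturationError(TranspirestError):
    """A vapour concentration exceeds saturation at the given temperature."""


class NoTranspirationError(TranspirestError):
    """Transpiration rate is zero or negative; resistance is undefined."""


class DrivingForceError(TranspirestError):
    """Ambient vapour concentration at or above the intercellular one."""


class ResistanceInconsistencyError(TranspirestError):
    """A resistance partition would produce a negative component."""


class InsufficientDataError(TranspirestError):
    """Too few or degenerate data points for the requested estimate."""


class ParseError(TranspirestError):
    """A CSV file does not conform to the expected schema."""


class DataValidationError(TranspirestError):
    """Parsed data violate an invariant (monotone time, mass > 0, ...)."""


class CoverageError(TranspirestError):
    """A climate log does not cover the requested averaging window."""


class CalibrationRangeWarning(UserWarning):
    """Produce mass outside the calibrated range of a surface-area regression."""


class AssumptionWarning(UserWarning):
    """A documented default was substituted for a missing measurement."""


class CondensationWarning(UserWarning):
    """A weighing series gained mass; condensation or handling artefact."""
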