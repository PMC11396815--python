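"""Exception hierarchy for the smcfusion pipeline.

Every stage raises a subclass of :class:`SMCFusionError`, so callers can
distinguish configuration mistakes from degenerate data (empty masks, zero
denominators) without parsing messages.
"""


class SMCFusionError(Exception):
    """Base class for all smcfusion errors."""


class ConfigurationError(SMCFusionError):
    """An invalid configuration value; the message names the offending field."""


class DomainError(SMCFusionError):
    """Inputs violate a precondition (impossible masses, empty list, ...)."""


class MaskingError(SMCFusionError):
    """Canopy/soil masking produced an unusable (empty) region."""


class UndefinedValueError(SMCFusionError):
    """A formula denominator is exactly zero; the value is recorded missing."""


class CalibrationError(SMCFusionError):
    """Thermal calibration is impossible (too few or degenerate points)."""


class SearchError(SMCFusionError):
    """Every candidate in an exhaustive search was degenerate."""
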