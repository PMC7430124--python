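"""Exception hierarchy shared across the pipeline."""


class ThermalTimeError(Exception):
    """Base class for all package-specific errors."""


class TreatmentCodeError(ThermalTimeError):
    """A treatment code string does not follow the <Pop><Tm><C|A><dT>DT<n>d grammar."""


class CensusValidationError(ThermalTimeError):
    """A census table violates a time-course invariant (monotonicity, bounds, duplicates)."""


class PercentileNotReached(ThermalTimeError):
    """The cumulative curve never reaches the requested percentile.

    This is a signal, not an abort: callers exclude the treatment from the
    affected regressions (right-censoring at the final census).
    """


class UndefinedCurveError(ThermalTimeError):
    """A cumulative fraction cannot be formed (e.g. basis='final' with zero germination)."""


class InsufficientDataError(ThermalTimeError):
    """Too few observations for the requested fit."""


class DegenerateFitError(ThermalTimeError):
    """The response has no usable variation (all fractions equal, flat profile)."""


class OrientationError(ThermalTimeError):
    """A fitted slope has the wrong sign for a physically meaningful model."""


class SubBaseTemperatureError(ThermalTimeError):
    """Mean temperature at or below the base temperature: no thermal accumulation."""
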