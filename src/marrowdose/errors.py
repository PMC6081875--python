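"""Exception hierarchy for marrowdose.

All package-specific failures derive from :class:`MarrowDoseError` so callers
can catch the whole family; subclasses distinguish data problems (too few
samples, inconsistent quantification) from physics problems (a time-activity
series that does not decay) and configuration problems (missing organ masses
or S values).
"""


class MarrowDoseError(Exception):
    """Base class for all marrowdose errors."""


class InsufficientDataError(MarrowDoseError):
    """Too few measurement points for the requested fit."""


class NonPhysicalKineticsError(MarrowDoseError):
    """A fitted decay constant is non-positive (activity does not wash out).

    Carries the offending fitted value in :attr:`fitted_lambda`.
    """

    def __init__(self, message: str, fitted_lambda: float | None = None):
        super().__init__(message)
        self.fitted_lambda = fitted_lambda


class FitFailureError(MarrowDoseError):
    """Non-linear fit failed to converge; carries the best residual seen."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class NonIntegrableError(MarrowDoseError):
    """A time-activity curve with a non-positive decay constant has no finite
    integral to infinity."""


class ShapeError(MarrowDoseError):
    """Image or volume arrays have inconsistent shapes."""


class DomainError(MarrowDoseError):
    """An input value lies outside its physical domain."""


class CalibrationError(MarrowDoseError):
    """Planar or attenuation calibration cannot be established."""


class MissingSegmentError(MarrowDoseError):
    """A body segment has neither CT coverage nor a default attenuation value."""

    def __init__(self, message: str, label=None):
        super().__init__(message)
        self.label = label


class EmptyRegionError(MarrowDoseError):
    """A VOI or bounding region is empty (or all-zero)."""


class ConfigurationError(MarrowDoseError):
    """Missing or inconsistent phantom / patient configuration."""


class InconsistencyError(MarrowDoseError):
    """Quantified source activities are mutually inconsistent (e.g. the
    remainder-of-body time-integrated activity comes out negative)."""


class NonPhysicalSValueError(MarrowDoseError):
    """The mass-scaled remainder-of-body S-value bracket is non-positive."""


class AssemblyError(MarrowDoseError):
    """A dose report cannot be assembled from the given components."""


class UndefinedCorrelationError(MarrowDoseError):
    """Correlation is undefined (zero variance in one of the inputs)."""


class SpecError(MarrowDoseError):
    """A virtual-patient specification violates its invariants."""
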