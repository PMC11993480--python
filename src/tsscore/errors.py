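"""Exception hierarchy for the tsscore package."""


class TssError(Exception):
    """Base class for all tsscore errors."""


class InvalidMeasurementError(TssError, ValueError):
    """A radiographic measurement violates its physical domain."""


class OutOfHeadError(InvalidMeasurementError):
    """Projected screw centre lies outside the femoral-head circle."""


class DomainError(TssError, ValueError):
    """A categorical or integer input is outside its allowed domain."""


class FeasibilityError(TssError, ValueError):
    """Requested moments are not achievable on the discrete support."""


class CalibrationError(TssError, RuntimeError):
    """Copula calibration could not reach the target dispersion."""


class SeparationError(TssError, RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


class SingularDesignError(TssError, ValueError):
    """Design matrix is rank deficient (collinear or constant column)."""


class GroupingError(TssError, ValueError):
    """Too few distinct predictions to form calibration groups."""


class UndefinedCorrelationError(TssError, ValueError):
    """Rank correlation undefined (a constant input vector)."""


class SchemaError(TssError, ValueError):
    """Tabular input is missing required columns or is empty."""
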