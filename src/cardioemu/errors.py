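"""Exception hierarchy shared across the package."""


class CardioEmuError(Exception):
    """Base class for all package-specific errors."""


class InvalidStateError(CardioEmuError):
    """A cell state contains non-finite or physically impossible values."""


class ProtocolError(CardioEmuError):
    """A stimulation protocol run failed; carries the conductance vector."""

    def __init__(self, message, conductances=None):
        super().__init__(message)
        self.conductances = conductances


class NoActionPotentialError(CardioEmuError):
    """No upstroke was detected in a trace (max dV/dt below threshold)."""


class CensoredMeasurementError(CardioEmuError):
    """Repolarisation did not reach the threshold before the trace ended."""


class InsufficientCurveError(CardioEmuError):
    """Too few restitution points for a three-parameter exponential fit."""


class RestitutionFitError(CardioEmuError):
    """Simplex minimisation of the restitution fit failed to converge."""


class DatasetError(CardioEmuError):
    """Design-set generation failed for too many points."""


class FormatError(CardioEmuError):
    """A dataset file does not follow the expected CSV layout."""


class ConditioningError(CardioEmuError):
    """A correlation/covariance matrix stayed ill-conditioned after nugget
    escalation."""


class DegenerateOutputError(CardioEmuError):
    """An output column has (numerically) zero variance."""


class TransformError(CardioEmuError):
    """A requested column transform is not applicable (e.g. log of a
    non-positive value)."""


class RangeWarning(UserWarning):
    """A conductance lies outside the design input range."""
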