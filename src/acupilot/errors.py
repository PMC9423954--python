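"""Exception hierarchy shared across the toolkit."""


class AcupilotError(Exception):
    """Base class for all toolkit errors."""


class InsufficientDataError(AcupilotError):
    """Too few correspondences, beats, or samples for the requested fit."""


class DegenerateConfigurationError(AcupilotError):
    """Input geometry is rank-deficient (e.g. collinear control points)."""


class SingularTransformError(AcupilotError):
    """A transform matrix is singular or cannot be normalized."""


class HorizonPointError(AcupilotError):
    """A perspective denominator vanished at the evaluation point."""


class PointBehindCameraError(AcupilotError):
    """Model points fell behind the camera plane under the given pose."""

    def __init__(self, names):
        self.names = list(names)
        super().__init__(f"points behind camera: {', '.join(self.names)}")


class PoseInfeasibleError(AcupilotError):
    """Not enough consistent landmark correspondences to estimate a pose."""
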