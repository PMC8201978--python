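"""Exception hierarchy for aquadust."""


class AquadustError(Exception):
    """Base class for all aquadust-specific errors."""


class DomainError(AquadustError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class ConvergenceError(AquadustError, RuntimeError):
    """A numerical solver failed to converge; the message carries diagnostics."""


class CalibrationError(AquadustError, ValueError):
    """Single-point calibration cannot reach the requested efficiency."""


class UncalibratedModelError(AquadustError, RuntimeError):
    """An operation requiring a calibrated reporter model was called before calibration."""


class OutOfRangeError(AquadustError, ValueError):
    """A FRET efficiency falls outside the attainable range of the calibration curve.

    ``kind`` distinguishes readings wetter than saturation from readings drier
    than the inversion search floor.
    """

    def __init__(self, message: str, kind: str, zeta: float | None = None):
        super().__init__(message)
        self.kind = kind  # "wetter_than_saturation" | "drier_than_floor"
        self.zeta = zeta


class SpectrumParseError(AquadustError, ValueError):
    """A spectrum table is malformed; the message names the offending line(s)."""


class IdentifiabilityError(AquadustError, ValueError):
    """Fewer observations than free parameters in a fit."""


class EmptyComparisonError(AquadustError, ValueError):
    """No observation could be matched to a prediction time step."""
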