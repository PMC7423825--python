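"""Exception hierarchy for simulation and analysis failures."""


class BiventError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(BiventError, ValueError):
    """A parameter violates its documented invariant."""


class IntegrationError(BiventError):
    """ODE integration failed; carries the last valid state."""

    def __init__(self, message, last_state=None, last_time=None):
        super().__init__(message)
        self.last_state = last_state
        self.last_time = last_time


class PhysiologyViolationError(BiventError):
    """Simulation produced a physically impossible state (e.g. negative chamber volume)."""


class ShockInductionFailure(BiventError):
    """Stopping criteria unreachable within the allowed number of injections."""

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory or []


class CohortSamplingError(BiventError):
    """Could not draw a valid animal within the redraw budget."""


class InsufficientBeatsError(BiventError):
    """Fewer usable beats than the operation requires."""


class SegmentationError(BiventError):
    """No cardiac periodicity detected in the signals."""


class FiducialError(BiventError):
    """End-diastole / end-systole detection failed (e.g. v0 reference too large)."""


class OpenLoopError(BiventError):
    """PV trajectory does not close within tolerance."""


class InvalidBeatError(BiventError):
    """Beat-level quantity undefined (e.g. non-positive stroke volume)."""


class DegenerateFitError(BiventError):
    """Regression geometry is degenerate (no intersection / negative slope)."""


class CalibrationSanityError(BiventError):
    """Calibrated volumes are grossly non-physiological."""


class TitrationFailure(BiventError):
    """No dose on the grid reaches the MAP threshold."""

    def __init__(self, message, achieved_map=None):
        super().__init__(message)
        self.achieved_map = achieved_map


class InsufficientDataError(BiventError):
    """Too few values for a summary or comparison."""


class FormatError(BiventError):
    """Signal file or sidecar violates the interchange format."""


class ConfigError(BiventError):
    """Scenario configuration failed schema validation."""
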