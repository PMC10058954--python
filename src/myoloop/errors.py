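"""Exception hierarchy shared across the simulator."""


class MyoloopError(Exception):
    """Base class for all package errors."""


class ParameterError(MyoloopError, ValueError):
    """A model parameter violates one of its invariants."""


class DrugError(MyoloopError, ValueError):
    """A drug specification is inconsistent or unknown."""


class StepSizeError(MyoloopError, RuntimeError):
    """A time step was too large for the explicit part of an update."""


class ConvergenceError(MyoloopError, RuntimeError):
    """An iterative solve hit its iteration cap.

    Carries the residual history so callers can inspect how the
    iteration behaved before failing.
    """

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


class MeshError(MyoloopError, ValueError):
    """A finite-element mesh is invalid (e.g. non-positive Jacobian)."""


class ConfigError(MyoloopError, ValueError):
    """A configuration block is missing or malformed."""
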