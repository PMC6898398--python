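"""Shared exception types for the virtual instrument."""


class ConfigurationError(ValueError):
    """A parameter set violates a model or protocol invariant."""


class CalibrationError(ValueError):
    """Calibration data are insufficient or degenerate."""


class NoSurfaceError(RuntimeError):
    """The descent trace never crossed the feedback setpoint."""


class CollisionError(RuntimeError):
    """A constant-height trajectory would intersect the sample."""


class EstimationError(RuntimeError):
    """A trace or profile does not contain the feature being estimated."""
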