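"""Exception hierarchy shared across the package."""


class FetalPbkError(Exception):
    """Base class for package errors."""


class ConfigurationError(FetalPbkError, ValueError):
    """A configuration or reference-data problem (names the offending field)."""


class SimulationError(FetalPbkError, RuntimeError):
    """ODE integration failed; carries the last accepted time if known."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class CalibrationError(FetalPbkError, RuntimeError):
    """A barrier calibration target could not be reached."""


class FitError(FetalPbkError, RuntimeError):
    """Parameter estimation failed to produce a finite objective."""
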