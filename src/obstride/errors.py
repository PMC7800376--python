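"""Exception types shared across the package."""


class ObstrideError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ObstrideError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class CalibrationError(ObstrideError, RuntimeError):
    """The requested calibration target cannot be reached."""


class QCError(ObstrideError, RuntimeError):
    """Tracking quality control failed (e.g., too many masked frames)."""


class AnalysisError(ObstrideError, RuntimeError):
    """An analysis precondition is not met (too few steps, length mismatch, ...)."""
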