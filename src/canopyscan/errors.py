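"""Exception hierarchy for the canopyscan pipeline.

Every stage raises a subclass of :class:`CanopyScanError` so that batch
drivers can map error classes onto exit codes.
"""


class CanopyScanError(Exception):
    """Base class for all canopyscan errors."""

    exit_code = 1


class CalibrationError(CanopyScanError):
    """The scanner calibration frame is internally inconsistent."""

    exit_code = 2


class ConfigurationError(CanopyScanError):
    """A run configuration or sector layout is invalid."""

    exit_code = 3


class InputError(CanopyScanError):
    """An input value is outside its physical domain."""

    exit_code = 4


class JoinError(CanopyScanError):
    """Time-stamp join of traits/weights/environment failed."""

    exit_code = 5


class FitError(CanopyScanError):
    """A regression fit is degenerate (e.g. zero variance in x)."""

    exit_code = 6
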