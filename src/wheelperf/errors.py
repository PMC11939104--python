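"""Exception hierarchy for the wheelperf pipeline.

Every stage raises a subclass of :class:`WheelperfError` so that callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class WheelperfError(Exception):
    """Base class for all wheelperf errors."""


class InvalidParameterError(WheelperfError, ValueError):
    """A physical or configuration parameter is out of its valid range."""


class InvalidRateError(InvalidParameterError):
    """Sampling rate too low for the requested filter cutoff."""


class InvalidCourseError(InvalidParameterError):
    """A course specification cannot be simulated (e.g. <2 waypoints)."""


class AlignmentError(WheelperfError, ValueError):
    """Two series that must share a time base have different lengths."""


class MissingSensorError(WheelperfError, KeyError):
    """A required sensor stream is absent from the recording."""


class NoMotionError(WheelperfError):
    """Velocity never exceeds the start-detection threshold."""


class IncompleteTestError(WheelperfError):
    """The trial never satisfies its end rule (10 m not reached, no
    start-line re-crossing, trace shorter than the Wingate window...)."""


class DegenerateTrialError(WheelperfError):
    """A coast-down trial without a usable deceleration segment."""


class InconsistentTrialError(WheelperfError):
    """Fitted coast-down slope is non-negative (the chair sped up)."""


class UnidentifiableSystemError(WheelperfError):
    """Coast-down trials share one load fraction; the two rolling
    resistance coefficients cannot be separated."""


class UnidentifiableFitError(WheelperfError):
    """Regression predictor is constant."""


class InvalidWindowError(WheelperfError):
    """Empty or inverted analysis window."""


class InvalidCycleError(WheelperfError):
    """Zero-length push cycle."""


class InvalidInputError(WheelperfError, ValueError):
    """Generic contract violation on user-supplied data."""


class ParseError(WheelperfError):
    """Malformed sensor or manifest file."""


class DependencyError(WheelperfError):
    """A pipeline stage was requested without its prerequisite stage."""
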