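"""Exception hierarchy for the pipeline."""


class ThreadMotionError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(ThreadMotionError):
    """A file is missing required columns or fields."""


class FormatError(ThreadMotionError):
    """A file parses but violates a structural invariant (e.g. non-uniform time)."""


class ScriptError(ThreadMotionError):
    """A motion script is empty, ill-timed, or jumps between non-adjacent orientations."""


class ParameterError(ThreadMotionError):
    """An operation received an invalid parameter value."""


class CalibrationError(ThreadMotionError):
    """Calibration could not derive a valid profile from the recording."""


class SegmentationError(ThreadMotionError):
    """The stream is too short to cut a single window."""
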