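"""Exception hierarchy for the facegaze package."""


class FaceGazeError(Exception):
    """Base class for all facegaze errors."""


class StreamParseError(FaceGazeError):
    """A stream or cohort file could not be parsed.

    Carries the 1-based line number of the first offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class StreamValidationError(FaceGazeError):
    """Stream content violates an invariant (bad hit codes, empty file, ...)."""


class BoundsError(FaceGazeError, IndexError):
    """A frame interval is inverted, empty, or outside the stream."""


class DegenerateSegmentError(FaceGazeError):
    """A segment contains no valid frames, so no rate can be formed."""


class DegenerateStreamError(DegenerateSegmentError):
    """A stream is too short for the requested partition (e.g. deciles)."""


class SingularFitError(FaceGazeError):
    """A model fit is degenerate (zero variance, collinearity) and cannot
    produce meaningful estimates."""


class ConfigError(FaceGazeError):
    """A synthetic-cohort or pipeline configuration is invalid."""


class UnsupportedConfigurationError(ConfigError):
    """A closed-form result was requested outside its domain of validity
    (e.g. stationary renewal expectations under a time-varying rate)."""
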