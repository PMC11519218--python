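"""Exception types raised across the pipeline."""


class TibiafitError(Exception):
    """Base class for all package-specific errors."""


class CalibrationError(TibiafitError, ValueError):
    """Population calibration violates its invariants."""


class GenerationError(TibiafitError, RuntimeError):
    """Synthetic anatomy parameters produce degenerate geometry."""


class LandmarkError(TibiafitError, ValueError):
    """Landmarks are missing, degenerate or inconsistent."""


class EmptySliceError(TibiafitError, RuntimeError):
    """The resection plane does not intersect the surface."""


class AmbiguousTopologyError(TibiafitError, RuntimeError):
    """The resection plane cuts the surface in more than one closed loop."""


class ParseError(TibiafitError, ValueError):
    """A tabular/JSON input file could not be parsed.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class UndefinedTestError(TibiafitError, ValueError):
    """A statistical test is undefined for the given input (e.g. constant data)."""
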