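"""Exception hierarchy for slidescope."""


class SlidescopeError(Exception):
    """Base class for all slidescope errors."""


class DimensionError(SlidescopeError):
    """Raster shapes that were required to match do not."""


class CalibrationError(SlidescopeError):
    """Brightfield/background calibration pair is unusable."""


class DegenerateMatrixError(SlidescopeError):
    """Stain matrix is singular or stain vectors are parallel."""


class ParameterError(SlidescopeError):
    """A parameter value is outside its admissible range."""


class TableParseError(SlidescopeError):
    """A tabular input file could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class InvalidTileError(SlidescopeError):
    """A subtile has no usable pixels for orientation analysis."""


class PipelineError(SlidescopeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
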