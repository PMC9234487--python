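"""Exception types shared across the toolkit."""


class ForestcastError(Exception):
    """Base class for all toolkit errors."""


class RasterIOError(ForestcastError):
    """A raster or manifest file could not be read or written."""


class BandNotFoundError(RasterIOError):
    """The requested band is not present in the file."""


class InvalidGeometryError(ForestcastError):
    """A boundary polygon is degenerate (fewer than 3 distinct vertices)."""


class ManifestParseError(RasterIOError):
    """A block-grid manifest is malformed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class EmptyStudyAreaError(ForestcastError):
    """The study-area mask contains no pixels."""


class InvalidParametersError(ForestcastError):
    """Window/stride parameters are inconsistent with the grid."""


class InsufficientFramesError(ForestcastError):
    """A block series has too few yearly frames for the requested statistic."""


class DivergenceError(ForestcastError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training loss at epoch {epoch}")


class IncompatibleCheckpointError(ForestcastError):
    """A model checkpoint does not match the expected format or config."""


class UndefinedMetricError(ForestcastError):
    """A metric is undefined for the given input (e.g. zero-variance truth)."""
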