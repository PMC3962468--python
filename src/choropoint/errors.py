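"""Exception hierarchy shared across the pipeline."""


class ChoropointError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChoropointError):
    """A raster file is not in an accepted format (e.g. unequal RGB channels)."""


class ShapeMismatchError(ChoropointError):
    """Two co-registered rasters do not share the same pixel dimensions."""


class NoVesselError(ChoropointError):
    """A vessel mask contains no foreground pixel, so no distance reference exists."""


class CapacityError(ChoropointError):
    """More distinct points were requested than the sampling region contains."""


class InsufficientDataError(ChoropointError):
    """A statistic requiring at least two samples was asked of fewer."""


class DegenerateVarianceError(ChoropointError):
    """All paired differences are identical; the t statistic is undefined."""


class GenerationError(ChoropointError):
    """A synthetic raster could not be produced within its stated tolerances."""


class EyeAnalysisError(ChoropointError):
    """A per-eye analysis hit a fatal condition (empty region, no vessels, no points)."""
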