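"""Exception hierarchy for the parmap pipeline."""


class ParmapError(Exception):
    """Base class for all parmap errors."""


class ValidationError(ParmapError, ValueError):
    """Invalid parameters or inputs."""


class SizingError(ValidationError):
    """Requested geometry does not fit the canvas."""


class SegmentationError(ParmapError):
    """Embryo segmentation failed (no object, blank image, ...)."""


class StraighteningError(ParmapError):
    """Cortex straightening failed; carries the offending positions."""

    def __init__(self, message, positions=None):
        super().__init__(message)
        self.positions = positions if positions is not None else []


class DegenerateFitError(ParmapError):
    """A regression or profile fit has no unique solution."""


class FitError(ParmapError):
    """Profile decomposition failed on too many positions."""


class SchemaError(ParmapError):
    """A table is missing required columns or has malformed values."""


class ConfigError(ParmapError):
    """Pipeline configuration invalid or inputs missing."""


class PipelineError(ParmapError):
    """Too many per-embryo failures to produce a cohort."""
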