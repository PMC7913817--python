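"""Exception hierarchy for the opportunistic QCT pipeline."""


class OpqctError(Exception):
    """Base class for all package errors."""


class GeometryError(OpqctError):
    """Invalid or colliding synthetic anatomy (names the offending labels)."""


class ParameterError(OpqctError):
    """Invalid user-supplied parameters (sample sizes, SDs, correlations ...)."""


class SamplingError(OpqctError):
    """Phantom phase ROI could not be sampled (cropped phantom, empty ROI)."""


class DegenerateFitError(OpqctError):
    """HU-to-BMD line cannot be fit (identical phase HU, non-positive slope)."""


class PlacementError(OpqctError):
    """Vertebral ROI cannot be placed inside the trabecular compartment."""


class MeasurementError(OpqctError):
    """BMD measurement failed (empty ROI, unknown level)."""


class WindowError(OpqctError):
    """The L4/5 slice window exceeds the volume extent."""


class LeakError(OpqctError):
    """Region growing leaked through the muscle wall.

    Carries the approximate breach location as ``(x, y, z)`` voxel indices.
    """

    def __init__(self, message: str, location=None):
        super().__init__(message)
        self.location = location


class MatchingError(OpqctError):
    """Cohort pair ids do not form a perfect 1:1 case-control matching."""


class FormatError(OpqctError):
    """Malformed input file (names the offending field)."""


class PipelineStageError(OpqctError):
    """A pipeline stage failed; names the stage and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
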