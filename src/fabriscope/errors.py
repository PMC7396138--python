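"""Exception hierarchy.

All package errors derive from :class:`FabriscopeError` so the CLI can map
any data/processing failure to a single exit code.
"""


class FabriscopeError(Exception):
    """Base class for all fabriscope errors."""


class UnrepresentableGeometryError(FabriscopeError):
    """Weave geometry cannot be rendered at the requested pixel scale."""


class DegenerateGridError(FabriscopeError):
    """Calibration-grid parameters leave fewer than two rulings in frame."""


class CalibrationError(FabriscopeError):
    """Grid counting failed (fewer than two detected line centers)."""


class TooSmallRegionError(FabriscopeError):
    """Focus crop would be smaller than the minimum analyzable size."""


class NoThresholdError(FabriscopeError):
    """Otsu thresholding is undefined (single-valued histogram)."""


class EmptyMaskError(FabriscopeError):
    """A coverage statistic was requested on a mask with no pixels."""


class ManifestError(FabriscopeError):
    """The mask manifest is missing, empty, or malformed."""


class PipelineError(FabriscopeError):
    """Every image in a pipeline run failed to process."""
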