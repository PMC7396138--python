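"""Pixel-scale calibration by counting grid periods of known pitch.

The microscope's field of view is measured by imaging a ruled calibration
slide (10 um minimum inter-grid distance) and counting how many whole
grid periods span the in-focus central region. The count times the known
pitch gives the field of view in micrometers; dividing by the pixel span
between the outermost counted line centers gives the scale in um/px.

Line detection is deliberately simple — grids are high-contrast by
design: average the focus crop into a 1D profile across the counting
axis, smooth it, threshold at the midpoint between profile extremes, and
take each below-threshold run as one ruling. Runs touching the profile
ends are discarded (they may be partial lines), matching the convention
of counting only whole grid periods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import CalibrationError
from .image import FabricImage
from .segmentation import crop_focus_region

__all__ = ["CalibrationResult", "count_grid_periods", "calibrate", "calibrate_both"]

_AXIS = {"x": 0, "y": 1}  # profile along x = mean over rows (axis 0), etc.


@dataclass(frozen=True)
class CalibrationResult:
    """Scale and field of view recovered from one grid image axis."""

    pitch_um: float
    grid_periods: int
    pixel_scale: float  # um / pixel
    fov_um: float  # grid_periods * pitch_um, by construction
    axis: str = "x"


def _line_centers(
    image: FabricImage,
    axis: str = "x",
    focus_fraction: float = 0.6,
    smooth_sigma_px: float = 1.0,
) -> np.ndarray:
    """Sub-pixel centers of whole dark rulings along one axis of the crop."""
    if axis not in _AXIS:
        raise ValueError("axis must be 'x' or 'y'")
    crop = crop_focus_region(image, focus_fraction)
    profile = crop.pixels.astype(float).mean(axis=_AXIS[axis])
    if smooth_sigma_px > 0:
        profile = gaussian_filter1d(profile, smooth_sigma_px, mode="nearest")
    lo, hi = profile.min(), profile.max()
    if hi - lo < 1.0:
        raise CalibrationError("no grid contrast in profile")
    dark = profile < (lo + hi) / 2.0

    # runs of consecutive dark samples; drop runs touching the profile ends
    padded = np.concatenate(([False], dark, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]
    keep = (starts > 0) & (stops < dark.size)
    centers = (starts[keep] + stops[keep] - 1) / 2.0
    if centers.size < 2:
        raise CalibrationError(
            f"found {centers.size} whole ruling(s); need at least 2"
        )
    return centers


def count_grid_periods(
    image: FabricImage,
    axis: str = "x",
    focus_fraction: float = 0.6,
    smooth_sigma_px: float = 1.0,
) -> int:
    """Number of whole dark-line periods spanning the analyzed extent."""
    return _line_centers(image, axis, focus_fraction, smooth_sigma_px).size - 1


def calibrate(
    image: FabricImage,
    pitch_um: float,
    axis: str = "x",
    focus_fraction: float = 0.6,
    smooth_sigma_px: float = 1.0,
) -> CalibrationResult:
    """Recover pixel scale and field of view from a grid image.

    ``fov_um = periods * pitch_um`` exactly; ``pixel_scale`` is that FOV
    divided by the pixel span between the outermost counted line centers.
    """
    if pitch_um <= 0:
        raise ValueError("pitch_um must be positive")
    centers = _line_centers(image, axis, focus_fraction, smooth_sigma_px)
    periods = centers.size - 1
    span_px = float(centers[-1] - centers[0])
    fov_um = periods * pitch_um
    return CalibrationResult(
        pitch_um=pitch_um,
        grid_periods=periods,
        pixel_scale=fov_um / span_px,
        fov_um=fov_um,
        axis=axis,
    )


def calibrate_both(
    image: FabricImage,
    pitch_um: float,
    focus_fraction: float = 0.6,
    smooth_sigma_px: float = 1.0,
) -> dict[str, CalibrationResult | float]:
    """Per-axis calibrations plus their mean pixel scale.

    Reporting both axes and their mean is a convention of this module;
    the grid-counting procedure itself does not prescribe one.
    """
    per_axis = {
        ax: calibrate(image, pitch_um, ax, focus_fraction, smooth_sigma_px)
        for ax in ("x", "y")
    }
    mean_scale = float(np.mean([r.pixel_scale for r in per_axis.values()]))
    return {**per_axis, "mean_pixel_scale": mean_scale}
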