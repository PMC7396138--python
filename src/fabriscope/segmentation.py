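"""Yarn/pore segmentation of fabric micrographs.

Ball-lens optics keep only the central region of a smartphone micrograph
in focus, so every analysis starts from a centered focus crop. Dense
weaves whose pores are barely visible get a percentile contrast stretch
before thresholding. Classification is a single global threshold: pixels
brighter than it are pore, the rest yarn (bright-field transmitted light
makes the inter-yarn openings the bright patches). The default threshold
is Otsu's between-class-variance maximizer for reproducibility; a manual
threshold — the classical interactive procedure — remains available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .errors import NoThresholdError, TooSmallRegionError
from .image import FabricImage

__all__ = [
    "BinaryPoreMask",
    "crop_focus_region",
    "stretch_contrast",
    "compute_threshold",
    "classify_pixels",
    "segment",
]

#: Smallest focus crop (pixels per side) still worth analyzing.
MIN_CROP_SIDE = 16


@dataclass
class BinaryPoreMask:
    """Binary pore/yarn partition of a (cropped) micrograph.

    ``labels`` is True where the pixel is pore (bright) and False where it
    is yarn (dark); every pixel belongs to exactly one class.
    """

    labels: np.ndarray
    threshold_used: float
    contrast_adjusted: bool = False
    pixel_scale: float | None = None
    mask_id: str | None = None
    layer: str | None = None
    region_index: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D boolean grid")

    @property
    def n_total(self) -> int:
        return int(self.labels.size)

    @property
    def n_pore(self) -> int:
        return int(self.labels.sum())

    @property
    def n_yarn(self) -> int:
        return self.n_total - self.n_pore


def crop_focus_region(image: FabricImage, fraction: float = 0.6) -> FabricImage:
    """Centered crop keeping ``fraction`` of each side (the in-focus area).

    Side lengths are rounded down; metadata and labels are preserved.
    Raises :class:`TooSmallRegionError` if the crop would be smaller than
    16x16 pixels.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1:
        return image.with_pixels(image.pixels)
    h, w = image.shape
    h2, w2 = int(h * fraction), int(w * fraction)
    if h2 < MIN_CROP_SIDE or w2 < MIN_CROP_SIDE:
        raise TooSmallRegionError(
            f"focus crop {h2}x{w2} px is below the {MIN_CROP_SIDE} px minimum"
        )
    r0, c0 = (h - h2) // 2, (w - w2) // 2
    return image.with_pixels(
        image.pixels[r0 : r0 + h2, c0 : c0 + w2], focus_fraction=fraction
    )


def stretch_contrast(
    image: FabricImage, low_pct: float = 1.0, high_pct: float = 99.0
) -> FabricImage:
    """Linear percentile stretch mapping [low, high] percentiles to [0, 255].

    Used for dense fabrics whose pores are not easily visible. A constant
    image is returned unchanged with ``meta["constant_image"]`` set.
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    lo, hi = np.percentile(image.pixels, [low_pct, high_pct])
    if hi <= lo:
        return image.with_pixels(image.pixels, constant_image=True)
    stretched = (image.pixels.astype(float) - lo) * (255.0 / (hi - lo))
    pixels = np.clip(np.round(stretched), 0, 255).astype(np.uint8)
    return image.with_pixels(pixels, contrast_stretched=True)


def compute_threshold(
    image: FabricImage,
    method: str = "otsu",
    manual_value: float | None = None,
) -> float:
    """Global intensity threshold separating yarn (dark) from pore (bright).

    ``otsu`` maximizes between-class variance over the 256-bin histogram;
    ``manual`` passes ``manual_value`` through (the interactive workflow).
    """
    if method == "manual":
        if manual_value is None:
            raise ValueError("manual thresholding requires manual_value")
        if not 0 <= manual_value <= 255:
            raise ValueError("manual_value must be in [0, 255]")
        return float(manual_value)
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    if manual_value is not None:
        raise ValueError("manual_value is only valid with method='manual'")
    if np.unique(image.pixels).size < 2:
        raise NoThresholdError("single-valued histogram: Otsu is undefined")
    return float(threshold_otsu(image.pixels, nbins=256))


def classify_pixels(image: FabricImage, threshold: float) -> BinaryPoreMask:
    """Partition pixels: intensity > threshold -> pore, else yarn."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    return BinaryPoreMask(
        labels=image.pixels > threshold,
        threshold_used=float(threshold),
        contrast_adjusted=bool(image.meta.get("contrast_stretched", False)),
        pixel_scale=image.pixel_scale,
        mask_id=image.mask_id,
        layer=image.layer,
        region_index=image.region_index,
    )


def segment(
    image: FabricImage,
    focus_fraction: float = 0.6,
    threshold_method: str = "otsu",
    manual_value: float | None = None,
    contrast_trigger_pore_fraction: float = 0.02,
    contrast_percentiles: tuple[float, float] = (1.0, 99.0),
) -> BinaryPoreMask:
    """Default segmentation pipeline: focus crop, threshold, classify.

    If the initial classification finds fewer than
    ``contrast_trigger_pore_fraction`` pore pixels — the barely-visible-
    pore regime of very dense weaves — the crop is contrast-stretched and
    re-thresholded, and the result is flagged ``contrast_adjusted``.
    """
    crop = crop_focus_region(image, focus_fraction)
    thr = compute_threshold(crop, threshold_method, manual_value)
    mask = classify_pixels(crop, thr)
    if (
        threshold_method == "otsu"
        and mask.n_pore / mask.n_total < contrast_trigger_pore_fraction
    ):
        stretched = stretch_contrast(crop, *contrast_percentiles)
        if stretched.meta.get("contrast_stretched"):
            thr = compute_threshold(stretched, "otsu")
            mask = classify_pixels(stretched, thr)
    return mask
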