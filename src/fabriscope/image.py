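"""Calibrated micrograph container and grayscale I/O.

A :class:`FabricImage` is an 8-bit grayscale intensity field plus the
acquisition metadata the rest of the pipeline needs: the pixel scale in
micrometers per pixel (absent until a calibration has been attached), the
mask the specimen came from, which of the two fabric layers was imaged, and
a region index distinguishing the 5-10 fields of view collected per layer.
Color phone-camera frames are reduced to grayscale with the standard
ITU-R BT.601 luma weights on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np

__all__ = ["FabricImage", "rgb_to_gray"]

#: BT.601 luma weights used to collapse RGB phone frames to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


def rgb_to_gray(pixels: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3) or (H, W, 4) uint8 frame to (H, W) luma."""
    rgb = np.asarray(pixels)[..., :3].astype(float)
    return np.clip(np.round(rgb @ _LUMA), 0, 255).astype(np.uint8)


@dataclass
class FabricImage:
    """One micrograph with its acquisition metadata.

    Parameters
    ----------
    pixels
        2D uint8 intensity array (0-255). Anything array-like and integral
        is accepted and cast.
    pixel_scale
        Micrometers per pixel; ``None`` until calibration is attached.
    mask_id, layer, region_index
        Specimen labels: mask identifier (e.g. ``"M6"``), fabric layer
        (``"L1"``/``"L2"``), and the index of the imaged region.
    meta
        Free-form provenance (synthetic ground truth, processing flags).
    """

    pixels: np.ndarray
    pixel_scale: float | None = None
    mask_id: str | None = None
    layer: str | None = None
    region_index: int | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 3:
            px = rgb_to_gray(px)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2D grayscale, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.pixel_scale is not None and not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be positive when present")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, **meta_updates: Any) -> "FabricImage":
        """Copy of this image with new pixel data and merged metadata."""
        out = replace(self, pixels=np.asarray(pixels))
        out.meta = {**self.meta, **meta_updates}
        return out

    def with_scale(self, pixel_scale: float) -> "FabricImage":
        return replace(self, pixel_scale=float(pixel_scale))

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        *,
        pixel_scale: float | None = None,
        mask_id: str | None = None,
        layer: str | None = None,
        region_index: int | None = None,
    ) -> "FabricImage":
        """Read a PNG/TIFF micrograph; RGB(A) input is converted to luma.

        A JSON sidecar (same stem, ``.json`` suffix) written by the
        synthetic generator is picked up into ``meta`` when present.
        """
        path = Path(path)
        raw = iio.imread(path)
        meta: dict[str, Any] = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            pixels=raw,
            pixel_scale=pixel_scale,
            mask_id=mask_id,
            layer=layer,
            region_index=region_index,
            meta=meta,
        )

    def save(self, path: str | Path, sidecar: bool = False) -> Path:
        """Write the image as 8-bit grayscale PNG (optionally + JSON meta)."""
        path = Path(path)
        iio.imwrite(path, self.pixels)
        if sidecar and self.meta:
            path.with_suffix(".json").write_text(json.dumps(self.meta, indent=2))
        return path
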