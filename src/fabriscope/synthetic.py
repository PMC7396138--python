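"""Synthetic plain-weave micrographs with exact analytic ground truth.

The generator renders an axis-aligned rectangular weave: warp yarns are
vertical strips of width ``warp_width`` repeating every ``warp_pitch``
micrometers along x, weft yarns the analogous horizontal strips along y.
A pixel is yarn iff its *center* falls inside a yarn strip on either axis
(bright-field convention: yarns dark, inter-yarn pores bright). On top of
the clean binary rendering the generator can add the optical artifacts of
a ball-lens smartphone microscope — isotropic Gaussian defocus blur,
radial vignetting that darkens the frame away from the in-focus center,
and additive sensor noise — none of which alter the ground truth, which is
computed from the geometry alone:

* true cover factor (percent of area occupied by yarn),
  ``100 * (1 - gap_x * gap_y / (warp_pitch * weft_pitch))``;
* pore gaps ``gap = pitch - width`` per axis and the pore's longest
  dimension, the diagonal ``sqrt(gap_x**2 + gap_y**2)``;
* the number of pore cells that rasterize fully inside the frame without
  touching its border (closed-form pixel arithmetic, not pixel counting).

Ruled calibration-grid images of known pitch are generated the same way,
with every line-center position recorded in metadata so grid-counting
calibration can be tested against an exact oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import DegenerateGridError, UnrepresentableGeometryError
from .image import FabricImage

__all__ = [
    "WeaveParams",
    "GroundTruth",
    "generate_weave_image",
    "generate_grid_image",
    "save_weave",
]


@dataclass(frozen=True)
class WeaveParams:
    """Geometry, optics and noise parameters of one synthetic weave.

    Pitches are center-to-center yarn spacings, widths the yarn strip
    widths, both in micrometers; ``warp_*`` runs along x (columns) and
    ``weft_*`` along y (rows). Intensities are 8-bit values with
    ``pore_intensity > yarn_intensity`` (pores are the bright patches).
    ``blur_sigma_px`` is the Gaussian defocus sigma in pixels,
    ``vignette_strength`` in [0, 1] the relative darkening at the frame
    corners, and ``noise_sd`` the additive Gaussian noise sigma in
    intensity units.
    """

    warp_pitch: float
    weft_pitch: float
    warp_width: float
    weft_width: float
    pixel_scale: float = 1.0
    image_size: tuple[int, int] = (512, 512)  # (height, width) px
    yarn_intensity: int = 60
    pore_intensity: int = 220
    noise_sd: float = 0.0
    blur_sigma_px: float = 0.0
    vignette_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.warp_width <= self.warp_pitch):
            raise ValueError("need 0 < warp_width <= warp_pitch")
        if not (0 < self.weft_width <= self.weft_pitch):
            raise ValueError("need 0 < weft_width <= weft_pitch")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if not (0 <= self.yarn_intensity < self.pore_intensity <= 255):
            raise ValueError(
                "need 0 <= yarn_intensity < pore_intensity <= 255 "
                "(bright-field: pores bright, yarns dark)"
            )
        if not (0 <= self.vignette_strength <= 1):
            raise ValueError("vignette_strength must be in [0, 1]")
        if self.noise_sd < 0 or self.blur_sigma_px < 0:
            raise ValueError("noise_sd and blur_sigma_px must be >= 0")

    @property
    def gap_x(self) -> float:
        return self.warp_pitch - self.warp_width

    @property
    def gap_y(self) -> float:
        return self.weft_pitch - self.weft_width


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth for one :class:`WeaveParams` rendering."""

    true_cover_factor: float  # percent, area-ratio definition
    true_pore_gap_x: float  # um
    true_pore_gap_y: float  # um
    true_pore_longest_dim: float  # um, gap-rectangle diagonal
    pore_count_expected: int  # pore cells fully interior to the frame


def _axis_gap_spans(
    pitch_um: float, width_um: float, scale: float, n_px: int
) -> list[tuple[int, int]]:
    """Pixel-index spans [c0, c1] of inter-yarn gaps along one axis.

    Uses the same pixel-center rule as the renderer, so the spans are an
    exact closed-form description of the rasterized gap columns/rows.
    """
    spans: list[tuple[int, int]] = []
    extent = n_px * scale
    k = 0
    while k * pitch_um < extent:
        lo = k * pitch_um + width_um  # gap start (um)
        hi = (k + 1) * pitch_um  # gap end (um), exclusive
        if hi > lo and lo < extent:
            c0 = max(int(math.ceil(lo / scale - 0.5)), 0)
            c1 = min(int(math.ceil(hi / scale - 0.5)) - 1, n_px - 1)
            if c1 >= c0:
                spans.append((c0, c1))
        k += 1
    return spans


def _ground_truth(params: WeaveParams) -> GroundTruth:
    p = params
    cover = 100.0 * (1.0 - (p.gap_x * p.gap_y) / (p.warp_pitch * p.weft_pitch))
    if p.gap_x <= 0 or p.gap_y <= 0:
        longest = 0.0
        count = 0
    else:
        longest = math.hypot(p.gap_x, p.gap_y)
        h, w = p.image_size
        x_spans = _axis_gap_spans(p.warp_pitch, p.warp_width, p.pixel_scale, w)
        y_spans = _axis_gap_spans(p.weft_pitch, p.weft_width, p.pixel_scale, h)
        nx = sum(1 for c0, c1 in x_spans if c0 >= 1 and c1 <= w - 2)
        ny = sum(1 for r0, r1 in y_spans if r0 >= 1 and r1 <= h - 2)
        count = nx * ny
    return GroundTruth(
        true_cover_factor=cover,
        true_pore_gap_x=p.gap_x,
        true_pore_gap_y=p.gap_y,
        true_pore_longest_dim=longest,
        pore_count_expected=count,
    )


def _render_binary(params: WeaveParams) -> np.ndarray:
    """Noise/blur-free rendering: values only in {yarn, pore} intensity."""
    h, w = params.image_size
    s = params.pixel_scale
    x_um = (np.arange(w) + 0.5) * s
    y_um = (np.arange(h) + 0.5) * s
    yarn_x = (x_um % params.warp_pitch) < params.warp_width
    yarn_y = (y_um % params.weft_pitch) < params.weft_width
    yarn = yarn_y[:, None] | yarn_x[None, :]
    img = np.where(yarn, params.yarn_intensity, params.pore_intensity)
    return img.astype(float)


def _vignette_field(shape: tuple[int, int], strength: float) -> np.ndarray:
    """Radial multiplicative darkening, 1 at center, 1-strength at corners."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (cy**2 + cx**2)
    return 1.0 - strength * r2


def generate_weave_image(params: WeaveParams) -> tuple[FabricImage, GroundTruth]:
    """Render a plain-weave micrograph and its analytic ground truth.

    Deterministic for a fixed ``params.seed``. Raises
    :class:`UnrepresentableGeometryError` if a yarn pitch spans fewer than
    2 pixels at the given scale, or if the frame is narrower than 3 pitch
    periods on either axis.
    """
    h, w = params.image_size
    s = params.pixel_scale
    for pitch, n_px, axis in (
        (params.warp_pitch, w, "x"),
        (params.weft_pitch, h, "y"),
    ):
        if pitch / s < 2:
            raise UnrepresentableGeometryError(
                f"{axis}-pitch {pitch} um is below 2 px at {s} um/px"
            )
        if n_px * s < 3 * pitch:
            raise UnrepresentableGeometryError(
                f"frame spans fewer than 3 {axis}-pitch periods"
            )

    img = _render_binary(params)
    if params.blur_sigma_px > 0:
        img = gaussian_filter(img, params.blur_sigma_px, mode="nearest")
    if params.vignette_strength > 0:
        img = img * _vignette_field(params.image_size, params.vignette_strength)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth = _ground_truth(params)
    fabric = FabricImage(
        pixels=pixels,
        pixel_scale=s,
        meta={"weave_params": asdict(params), "ground_truth": asdict(truth)},
    )
    return fabric, truth


def generate_grid_image(
    pitch_um: float,
    pixel_scale: float,
    image_size: tuple[int, int] = (512, 512),
    line_width_px: float = 3.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    background_intensity: int = 230,
    line_intensity: int = 40,
) -> FabricImage:
    """Render a ruled calibration grid of known pitch.

    Dark rulings run in both orientations at exact ``pitch_um`` spacing on
    a bright background, line centers at integer multiples of the pitch
    (in micrometers) from the frame origin. The exact line-center pixel
    positions along each axis are recorded in ``meta["grid"]`` so tests
    can use them as an oracle. The returned image carries *no*
    ``pixel_scale``: recovering it is the calibration module's job.
    """
    if pitch_um / pixel_scale < line_width_px + 2:
        raise DegenerateGridError(
            f"pitch {pitch_um} um spans {pitch_um / pixel_scale:.1f} px, "
            f"need at least line_width + 2 = {line_width_px + 2:.0f} px"
        )
    h, w = image_size
    pitch_px = pitch_um / pixel_scale

    def centers(n_px: int) -> list[float]:
        # line k is centered at k * pitch_um, i.e. pixel index k*pitch_px - 0.5
        out = []
        k = 0
        while k * pitch_px - 0.5 < n_px:
            out.append(k * pitch_px - 0.5)
            k += 1
        return out

    cx, cy = centers(w), centers(h)
    if len(cx) < 2 and len(cy) < 2:
        raise DegenerateGridError("fewer than two rulings fit in the frame")

    x = np.arange(w)
    y = np.arange(h)
    half = line_width_px / 2.0
    # distance from each pixel center to the nearest ruling center
    dx = np.abs((x + 0.5) % pitch_px)
    dx = np.minimum(dx, pitch_px - dx)
    dy = np.abs((y + 0.5) % pitch_px)
    dy = np.minimum(dy, pitch_px - dy)
    on_line = (dy[:, None] < half) | (dx[None, :] < half)
    img = np.where(on_line, line_intensity, background_intensity).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    return FabricImage(
        pixels=pixels,
        meta={
            "grid": {
                "pitch_um": pitch_um,
                "pixel_scale": pixel_scale,
                "line_width_px": line_width_px,
                "line_centers_x_px": cx,
                "line_centers_y_px": cy,
            }
        },
    )


def save_weave(image: FabricImage, path: str | Path) -> Path:
    """Write a generated weave as PNG plus a JSON parameter sidecar."""
    path = Path(path)
    image.save(path)
    path.with_suffix(".json").write_text(json.dumps(image.meta, indent=2))
    return path
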