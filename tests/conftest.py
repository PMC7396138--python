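"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive — O(n^2) pairwise distances,
exhaustive 256-threshold search, direct geometric membership — so they
stay independent of the optimized implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fabriscope.synthetic import WeaveParams

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ----------------------------------------------------------------- oracles


def brute_force_feret(coords: np.ndarray) -> float:
    """O(n^2) maximum pairwise distance between pixel centers."""
    pts = np.asarray(coords, dtype=float)
    if len(pts) < 2:
        return 0.0
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def brute_force_otsu(pixels: np.ndarray) -> int:
    """Exhaustive between-class-variance maximization over 256 thresholds.

    Returns the threshold t (pixels > t are foreground) with maximum
    between-class variance; ties resolve toward the lower threshold.
    """
    hist = np.bincount(pixels.ravel(), minlength=256).astype(float)
    total = hist.sum()
    best_t, best_var = 0, -1.0
    for t in range(255):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (np.arange(t + 1) * hist[: t + 1]).sum() / w0
        mu1 = (np.arange(t + 1, 256) * hist[t + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-9:
            best_var, best_t = var, t
    return best_t


def geometric_pore_truth(params: WeaveParams) -> np.ndarray:
    """True pore membership from the weave geometry (pixel-center rule)."""
    h, w = params.image_size
    s = params.pixel_scale
    x = (np.arange(w) + 0.5) * s
    y = (np.arange(h) + 0.5) * s
    gap_x = (x % params.warp_pitch) >= params.warp_width
    gap_y = (y % params.weft_pitch) >= params.weft_width
    return gap_y[:, None] & gap_x[None, :]


def integer_period_window(pixels: np.ndarray, params: WeaveParams) -> np.ndarray:
    """Crop a rendering to a whole number of weave periods per axis.

    The analytic cover factor is an area ratio of the periodic unit cell,
    so rasterization accuracy must be judged on a window spanning whole
    periods; a partial period at the frame edge would otherwise dominate
    the comparison with a windowing bias unrelated to rasterization.
    """
    h, w = pixels.shape
    s = params.pixel_scale
    wx = int(round(int(w * s / params.warp_pitch) * params.warp_pitch / s))
    wy = int(round(int(h * s / params.weft_pitch) * params.weft_pitch / s))
    return pixels[:wy, :wx]


def raster_bound_pct(params: WeaveParams) -> float:
    """Half-pixel-per-pitch rasterization tolerance on the cover factor."""
    return 100.0 * (
        0.5 * params.pixel_scale / params.warp_pitch
        + 0.5 * params.pixel_scale / params.weft_pitch
    )


def random_blob(rng: np.random.Generator, n_px: int) -> np.ndarray:
    """Connected random pixel region grown by a lazy random walk."""
    seen = {(0, 0)}
    frontier = [(0, 0)]
    while len(seen) < n_px:
        r, c = frontier[rng.integers(len(frontier))]
        dr, dc = [(0, 1), (0, -1), (1, 0), (-1, 0)][rng.integers(4)]
        nxt = (r + dr, c + dc)
        if nxt not in seen:
            seen.add(nxt)
            frontier.append(nxt)
    return np.array(sorted(seen))


def random_weave_params(rng: np.random.Generator, **overrides) -> WeaveParams:
    """Continuous (non-grid-aligned) random weave geometry, 512 px frame."""
    size = overrides.pop("image_size", (512, 512))
    scale = overrides.pop("pixel_scale", 1.0)
    kwargs = dict(pixel_scale=scale, image_size=size)
    for pitch_key, width_key, n_px in (
        ("warp_pitch", "warp_width", size[1]),
        ("weft_pitch", "weft_width", size[0]),
    ):
        max_pitch = n_px * scale / 3.0
        pitch = rng.uniform(20 * scale, min(80 * scale, max_pitch))
        kwargs[pitch_key] = pitch
        kwargs[width_key] = pitch * rng.uniform(0.25, 0.75)
    kwargs.update(overrides)
    return WeaveParams(**kwargs)


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


@pytest.fixture
def quarter_gap_params() -> WeaveParams:
    """200 um pitch, 100 um yarns: gap area is a quarter cell (cover 75%)."""
    return WeaveParams(
        warp_pitch=200,
        weft_pitch=200,
        warp_width=100,
        weft_width=100,
        pixel_scale=1.0,
        image_size=(700, 700),
    )
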