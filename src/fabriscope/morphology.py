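"""Pore detection and longest-dimension (max Feret) morphometry.

Pores are 8-connected components of bright pixels in the binary
segmentation. Each pore's size is reported as its *longest dimension*:
the maximum Euclidean distance between any two of its pixel centers (the
maximum Feret diameter on pixel centers), which is the upper-estimate
pore size a manual line-tool measurement approximates. It is computed
exactly via the convex hull of the pixel centers followed by rotating
calipers over the hull's antipodal vertex pairs; a single-pixel pore has
longest dimension 0 by convention.

Pores touching the crop border have truncated extents; they are flagged
and excluded from sizing (they still count toward cover factor, which is
a pixel fraction of the whole analyzed area).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .segmentation import BinaryPoreMask

__all__ = [
    "PoreRegion",
    "PoreSizeResult",
    "label_pores",
    "longest_dimension",
    "max_feret_px",
    "pore_sizes_um",
]


@dataclass
class PoreRegion:
    """One connected bright component of the pore mask."""

    pixel_coords: np.ndarray  # (n, 2) array of (row, col)
    area_px: int
    centroid: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    touches_border: bool
    longest_dim_px: float
    pixel_scale: float | None = None

    @property
    def longest_dim_um(self) -> float | None:
        if self.pixel_scale is None:
            return None
        return self.longest_dim_px * self.pixel_scale

    @property
    def area_um2(self) -> float | None:
        if self.pixel_scale is None:
            return None
        return self.area_px * self.pixel_scale**2


@dataclass(frozen=True)
class PoreSizeResult:
    """The k largest interior pore sizes in micrometers.

    ``shortfall`` is True when fewer than k interior (non-border) pores
    were available, so the list is shorter than requested.
    """

    sizes_um: tuple[float, ...]
    shortfall: bool
    k_requested: int


def _collinear_diameter(pts: np.ndarray) -> float:
    """Diameter of a degenerate (collinear) point set via projection."""
    d = pts - pts[0]
    norms = np.einsum("ij,ij->i", d, d)
    far = d[int(np.argmax(norms))]
    n = math.sqrt(far @ far)
    if n == 0:
        return 0.0
    proj = d @ (far / n)
    return float(proj.max() - proj.min())


def _calipers_diameter(hull_pts: np.ndarray) -> float:
    """Rotating calipers over antipodal pairs of a convex polygon.

    ``hull_pts`` must be the hull vertices in counterclockwise order.
    Falls back to the exact pairwise maximum if the antipodal walk
    degenerates (near-collinear hulls).
    """
    n = len(hull_pts)
    if n <= 2:
        return 0.0 if n < 2 else float(np.linalg.norm(hull_pts[1] - hull_pts[0]))

    def cross(o: np.ndarray, a: np.ndarray) -> float:
        return float(o[0] * a[1] - o[1] * a[0])

    best = 0.0
    j = 1
    steps = 0
    for i in range(n):
        ni = (i + 1) % n
        edge = hull_pts[ni] - hull_pts[i]
        # advance j while the next vertex is farther from edge (i, ni)
        while cross(edge, hull_pts[(j + 1) % n] - hull_pts[j]) > 0:
            j = (j + 1) % n
            steps += 1
            if steps > 2 * n:  # degenerate hull: exact fallback
                diff = hull_pts[:, None, :] - hull_pts[None, :, :]
                return float(np.sqrt((diff**2).sum(-1)).max())
        best = max(
            best,
            float(np.linalg.norm(hull_pts[i] - hull_pts[j])),
            float(np.linalg.norm(hull_pts[ni] - hull_pts[j])),
        )
    return best


def max_feret_px(coords: np.ndarray) -> float:
    """Maximum Euclidean distance between pixel centers of a region.

    Exact: convex hull then rotating calipers. 0 for a single pixel.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    if len(pts) < 2:
        return 0.0
    if len(pts) == 2:
        return float(np.linalg.norm(pts[1] - pts[0]))
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return _collinear_diameter(pts)
    return _calipers_diameter(pts[hull.vertices])


def longest_dimension(region: "PoreRegion | np.ndarray") -> float:
    """Longest dimension (max Feret over pixel centers) in pixels."""
    if isinstance(region, PoreRegion):
        return max_feret_px(region.pixel_coords)
    return max_feret_px(region)


def label_pores(
    mask: BinaryPoreMask,
    min_area_px: int = 9,
    pixel_scale: float | None = None,
) -> list[PoreRegion]:
    """Extract pore regions as 8-connected bright components.

    Components smaller than ``min_area_px`` (noise specks) are dropped;
    components meeting the crop boundary are flagged ``touches_border``.
    Regions are ordered by the (top, left) corner of their bounding box.
    ``pixel_scale`` defaults to the scale carried on the mask.
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    scale = pixel_scale if pixel_scale is not None else mask.pixel_scale
    h, w = mask.labels.shape
    labeled = cc_label(mask.labels, connectivity=2)
    regions: list[PoreRegion] = []
    for props in regionprops(labeled):
        if props.area < min_area_px:
            continue
        r0, c0, r1, c1 = props.bbox
        coords = np.asarray(props.coords)
        regions.append(
            PoreRegion(
                pixel_coords=coords,
                area_px=int(props.area),
                centroid=tuple(props.centroid),
                bbox=(r0, c0, r1, c1),
                touches_border=bool(r0 == 0 or c0 == 0 or r1 == h or c1 == w),
                longest_dim_px=max_feret_px(coords),
                pixel_scale=scale,
            )
        )
    regions.sort(key=lambda r: (r.bbox[0], r.bbox[1]))
    return regions


def pore_sizes_um(
    regions: list[PoreRegion],
    pixel_scale: float,
    k: int = 10,
) -> PoreSizeResult:
    """The k largest interior pore sizes, in micrometers, descending.

    Border-touching pores are excluded (their extents are truncated by
    the crop). If fewer than k interior pores exist, all are returned
    with ``shortfall`` set.
    """
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    interior = sorted(
        (r.longest_dim_px * pixel_scale for r in regions if not r.touches_border),
        reverse=True,
    )
    return PoreSizeResult(
        sizes_um=tuple(interior[:k]),
        shortfall=len(interior) < k,
        k_requested=k,
    )
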