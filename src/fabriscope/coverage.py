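"""Cover factor and porosity from the binary classification.

Cover factor f' is the percentage of analyzed pixels classified as yarn,
the pixel-count estimate of the true area fraction covered by yarns;
porosity is its exact complement, 100 - f'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import EmptyMaskError
from .segmentation import BinaryPoreMask

__all__ = ["FabricMeasurement", "cover_factor", "porosity"]


def cover_factor(mask: BinaryPoreMask) -> float:
    """Percent of pixels classified as yarn, 100 * n_yarn / n_total."""
    if mask.n_total == 0:
        raise EmptyMaskError("cover factor undefined on an empty mask")
    return 100.0 * mask.n_yarn / mask.n_total


def porosity(cover_factor_pct: float) -> float:
    """Percent open area: the exact complement 100 - cover factor."""
    if not 0 <= cover_factor_pct <= 100:
        raise ValueError("cover factor must be in [0, 100]")
    return 100.0 - cover_factor_pct


@dataclass
class FabricMeasurement:
    """Per-image measurement: coverage plus interior pore sizes."""

    cover_factor_pct: float
    porosity_pct: float
    n_yarn: int
    n_total: int
    pore_sizes_um: tuple[float, ...] = ()
    mask_id: str | None = None
    layer: str | None = None
    region_index: int | None = None
    threshold_used: float | None = None
    contrast_adjusted: bool = False
    pore_shortfall: bool = False
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_mask(
        cls,
        mask: BinaryPoreMask,
        pore_sizes_um: tuple[float, ...] = (),
        pore_shortfall: bool = False,
    ) -> "FabricMeasurement":
        cf = cover_factor(mask)
        return cls(
            cover_factor_pct=cf,
            porosity_pct=porosity(cf),
            n_yarn=mask.n_yarn,
            n_total=mask.n_total,
            pore_sizes_um=tuple(pore_sizes_um),
            mask_id=mask.mask_id,
            layer=mask.layer,
            region_index=mask.region_index,
            threshold_used=mask.threshold_used,
            contrast_adjusted=mask.contrast_adjusted,
            pore_shortfall=pore_shortfall,
        )
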