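"""Per-fabric aggregation, ranking and the screening report.

Each (mask, layer) fabric is summarized as mean ± sigma pore size over
the k largest interior pores pooled across its region images (k = 10 by
default) and mean ± sigma cover factor over per-region values (first 5
regions by default), with sigma the sample standard deviation (n - 1).

Fabrics are then ranked for screening: smaller pores first, ties broken
by higher yarn packing (cover factor), then by mask id. Two fixed
reference sizes flag fabrics whose mean pore exceeds the bio-aerosol
scale (5 um) or the upper end of the respiratory-droplet range (100 um).
The report ranks and flags only — pore geometry gives a preliminary idea
of facemask quality, not a filtration-efficiency measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import FabricMeasurement

__all__ = [
    "AEROSOL_REF_UM",
    "DROPLET_REF_UM",
    "MaskRecord",
    "FabricSummary",
    "ScreeningReport",
    "summarize_fabric",
    "rank_fabrics",
    "extremes",
    "summaries_to_frame",
]

#: Bio-aerosol upper reference size (um).
AEROSOL_REF_UM = 5.0
#: Respiratory-droplet upper reference size (um).
DROPLET_REF_UM = 100.0


@dataclass(frozen=True)
class MaskRecord:
    """A two-layer cloth mask: type I (same fabric both layers) or II."""

    mask_id: str
    mask_type: str  # "I" or "II"
    layers: tuple[tuple[str, str], ...]  # (layer label, fabric description)

    def __post_init__(self) -> None:
        if self.mask_type not in ("I", "II"):
            raise ValueError("mask_type must be 'I' or 'II'")
        fabrics = [f for _, f in self.layers]
        if self.mask_type == "I" and len(set(fabrics)) > 1:
            raise ValueError("type I masks have the same fabric in both layers")
        if self.mask_type == "II" and (
            len(self.layers) != 2 or fabrics[0] == fabrics[1]
        ):
            raise ValueError("type II masks have exactly two distinct fabrics")


@dataclass(frozen=True)
class FabricSummary:
    """Mean ± sigma aggregates for one (mask, layer) fabric."""

    mask_id: str
    layer: str
    pore_size_mean_um: float
    pore_size_sd_um: float
    cover_factor_mean_pct: float
    cover_factor_sd_pct: float
    porosity_mean_pct: float
    n_pore: int
    n_regions: int
    mask_type: str = "I"
    fabric: str = ""
    single_observation: bool = False

    def __post_init__(self) -> None:
        if self.pore_size_sd_um < 0 or self.cover_factor_sd_pct < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_pore < 1 or self.n_regions < 1:
            raise ValueError("need at least one pore and one region")


@dataclass(frozen=True)
class ScreeningReport:
    """Ranked fabric summaries with reference-size flags."""

    ranked: tuple[FabricSummary, ...]
    exceeds_aerosol_size: dict[tuple[str, str], bool] = field(default_factory=dict)
    exceeds_droplet_range: dict[tuple[str, str], bool] = field(default_factory=dict)
    recommendation: tuple[str, str] = ("", "")  # (mask_id, layer)
    aerosol_ref_um: float = AEROSOL_REF_UM
    droplet_ref_um: float = DROPLET_REF_UM


def _sample_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def summarize_fabric(
    measurements: list[FabricMeasurement],
    k_pores: int = 10,
    n_regions_for_cover: int = 5,
    mask_type: str = "I",
    fabric: str = "",
) -> FabricSummary:
    """Aggregate per-region measurements of one (mask, layer) fabric.

    Pore statistics pool the interior pore sizes of all regions and keep
    the ``k_pores`` largest; cover-factor statistics use the first
    ``n_regions_for_cover`` regions in region order.
    """
    if not measurements:
        raise ValueError("need at least one measurement")
    ms = sorted(
        measurements,
        key=lambda m: (m.region_index if m.region_index is not None else 0),
    )
    pooled = np.sort(np.concatenate([np.asarray(m.pore_sizes_um) for m in ms]))[::-1]
    if pooled.size == 0:
        raise ValueError("no interior pores across measurements; cannot summarize")
    pores = pooled[:k_pores]
    covers = np.array([m.cover_factor_pct for m in ms[:n_regions_for_cover]])
    cf_mean = float(covers.mean())
    return FabricSummary(
        mask_id=ms[0].mask_id or "",
        layer=ms[0].layer or "L1",
        pore_size_mean_um=float(pores.mean()),
        pore_size_sd_um=_sample_sd(pores),
        cover_factor_mean_pct=cf_mean,
        cover_factor_sd_pct=_sample_sd(covers),
        porosity_mean_pct=100.0 - cf_mean,
        n_pore=int(pores.size),
        n_regions=int(covers.size),
        mask_type=mask_type,
        fabric=fabric,
        single_observation=bool(pores.size == 1 or covers.size == 1),
    )


def rank_fabrics(
    summaries: list[FabricSummary],
    aerosol_ref_um: float = AEROSOL_REF_UM,
    droplet_ref_um: float = DROPLET_REF_UM,
) -> ScreeningReport:
    """Rank fabrics for screening and set reference-size flags.

    Ascending mean pore size; ties broken by descending cover factor,
    then mask id, then layer — a fully keyed, order-independent sort.
    The recommendation is the top-ranked (smallest-pore, tightest) fabric.
    """
    if not summaries:
        raise ValueError("need at least one summary")
    ranked = tuple(
        sorted(
            summaries,
            key=lambda s: (
                s.pore_size_mean_um,
                -s.cover_factor_mean_pct,
                s.mask_id,
                s.layer,
            ),
        )
    )
    aerosol = {
        (s.mask_id, s.layer): s.pore_size_mean_um > aerosol_ref_um for s in ranked
    }
    droplet = {
        (s.mask_id, s.layer): s.pore_size_mean_um > droplet_ref_um for s in ranked
    }
    return ScreeningReport(
        ranked=ranked,
        exceeds_aerosol_size=aerosol,
        exceeds_droplet_range=droplet,
        recommendation=(ranked[0].mask_id, ranked[0].layer),
        aerosol_ref_um=aerosol_ref_um,
        droplet_ref_um=droplet_ref_um,
    )


_FIELDS = {
    "pore_size": "pore_size_mean_um",
    "cover_factor": "cover_factor_mean_pct",
    "porosity": "porosity_mean_pct",
}


def extremes(
    summaries: list[FabricSummary],
    fieldname: str = "cover_factor",
    layer_scope: str = "all",
) -> tuple[FabricSummary, FabricSummary]:
    """(minimum, maximum) summary for a field over the requested scope.

    ``layer_scope``: ``"all"`` for every (mask, layer) entry, or
    ``"type_i"`` restricting to type I masks. Ties resolve by mask id.
    """
    if fieldname not in _FIELDS:
        raise ValueError(f"field must be one of {sorted(_FIELDS)}")
    if layer_scope not in ("all", "type_i"):
        raise ValueError("layer_scope must be 'all' or 'type_i'")
    pool = [s for s in summaries if layer_scope == "all" or s.mask_type == "I"]
    if not pool:
        raise ValueError("no summaries in requested scope")
    attr = _FIELDS[fieldname]
    key = lambda s: (getattr(s, attr), s.mask_id, s.layer)  # noqa: E731
    return min(pool, key=key), max(pool, key=key)


def summaries_to_frame(summaries: list[FabricSummary]) -> pd.DataFrame:
    """Summary table with one row per (mask, layer) fabric."""
    return pd.DataFrame(
        [
            {
                "mask_id": s.mask_id,
                "mask_type": s.mask_type,
                "layer": s.layer,
                "fabric": s.fabric,
                "pore_size_mean_um": s.pore_size_mean_um,
                "pore_size_sd_um": s.pore_size_sd_um,
                "cover_factor_mean_pct": s.cover_factor_mean_pct,
                "cover_factor_sd_pct": s.cover_factor_sd_pct,
                "porosity_mean_pct": s.porosity_mean_pct,
                "n_pore": s.n_pore,
                "n_regions": s.n_regions,
            }
            for s in summaries
        ]
    )
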