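"""Bundled reference survey of sixteen two-layer cloth facemasks.

Smartphone-microscope measurements of sixteen commercial cloth masks,
M1-M16, bundled as the package's worked-example dataset: twelve type I
masks (same fabric in both layers, one fabric entry each) and four
type II masks (two distinct fabric layers, L1/L2 reported separately).
Each entry carries the mean ± sigma pore size (longest dimension, um,
over ten measurements) and cover factor (percent, over five region
images). These printed aggregates can be re-ingested as
:class:`~fabriscope.screening.FabricSummary` objects so that ranking,
extreme-finding and reporting run on them exactly as on freshly
measured fabrics.
"""

from __future__ import annotations

import pandas as pd

from .screening import FabricSummary

__all__ = ["REFERENCE_MEASUREMENTS", "reference_summaries", "reference_table"]

# mask_id, type, layer, fabric, pore mean, pore sd, cover mean, cover sd
REFERENCE_MEASUREMENTS: tuple[tuple[str, str, str, str, float, float, float, float], ...] = (
    ("M1", "I", "L1", "polyester-spandex", 394, 38, 78, 4),
    ("M2", "I", "L1", "cotton", 167, 26, 87, 2),
    ("M3", "I", "L1", "cotton-spandex", 392, 41, 79, 2),
    ("M4", "I", "L1", "rayon-spandex", 370, 57, 72, 9),
    ("M5", "I", "L1", "cotton-spandex", 173, 19, 88, 2),
    ("M6", "I", "L1", "cotton", 77, 8, 94, 2),
    ("M7", "I", "L1", "cotton-spandex", 204, 23, 82, 3),
    ("M8", "I", "L1", "cotton-polyester", 197, 27, 87, 1),
    ("M9", "I", "L1", "polyester-spandex", 258, 27, 83, 2),
    ("M10", "I", "L1", "polyester-spandex", 457, 39, 66, 4),
    ("M11", "I", "L1", "cotton", 138, 15, 90, 3),
    ("M12", "I", "L1", "cotton", 80, 9, 96, 2),
    ("M13", "II", "L1", "cotton", 187, 14, 87, 2),
    ("M13", "II", "L2", "polyester-spandex", 336, 21, 76, 2),
    ("M14", "II", "L1", "polyester-spandex", 245, 15, 71, 2),
    ("M14", "II", "L2", "rayon-spandex", 374, 19, 68, 2),
    ("M15", "II", "L1", "cotton-spandex", 172, 16, 81, 3),
    ("M15", "II", "L2", "polyester", 723, 20, 42, 6),
    ("M16", "II", "L1", "cotton", 216, 15, 83, 3),
    ("M16", "II", "L2", "cotton-spandex", 179, 38, 80, 6),
)

#: Number of pore measurements behind each reference mean.
_N_PORE = 10
#: Number of region images behind each reference cover factor.
_N_REGIONS = 5


def reference_summaries(mask_type: str | None = None) -> list[FabricSummary]:
    """Reference measurements as FabricSummary objects.

    ``mask_type`` optionally restricts to ``"I"`` or ``"II"`` masks.
    """
    out = []
    for mid, mtype, layer, fabric, pmean, psd, cmean, csd in REFERENCE_MEASUREMENTS:
        if mask_type is not None and mtype != mask_type:
            continue
        out.append(
            FabricSummary(
                mask_id=mid,
                layer=layer,
                pore_size_mean_um=float(pmean),
                pore_size_sd_um=float(psd),
                cover_factor_mean_pct=float(cmean),
                cover_factor_sd_pct=float(csd),
                porosity_mean_pct=100.0 - float(cmean),
                n_pore=_N_PORE,
                n_regions=_N_REGIONS,
                mask_type=mtype,
                fabric=fabric,
            )
        )
    return out


def reference_table() -> pd.DataFrame:
    """Reference survey as a tidy DataFrame, one row per (mask, layer)."""
    return pd.DataFrame(
        REFERENCE_MEASUREMENTS,
        columns=[
            "mask_id",
            "mask_type",
            "layer",
            "fabric",
            "pore_size_mean_um",
            "pore_size_sd_um",
            "cover_factor_mean_pct",
            "cover_factor_sd_pct",
        ],
    )
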