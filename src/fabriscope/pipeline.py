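"""End-to-end pipeline: manifest in, screening report out.

``analyze_image`` measures one micrograph (focus crop, threshold, pore
morphometry, coverage); ``run_pipeline`` drives a whole mask manifest —
a CSV with one row per region image, columns ``mask_id, mask_type,
layer, fabric, image_path`` (plus optional ``region_index``) — through
measurement, per-fabric aggregation and ranking. Unreadable or
unprocessable images are recorded as per-image failures and skipped; the
run only aborts if every image fails. All outputs are deterministic for
fixed inputs and config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .coverage import FabricMeasurement
from .errors import FabriscopeError, ManifestError, PipelineError
from .image import FabricImage
from .morphology import label_pores, pore_sizes_um
from .screening import (
    FabricSummary,
    ScreeningReport,
    rank_fabrics,
    summaries_to_frame,
    summarize_fabric,
)
from .segmentation import segment

__all__ = ["analyze_image", "run_pipeline", "read_manifest", "write_report"]

log = logging.getLogger("fabriscope")

_MANIFEST_COLS = ("mask_id", "mask_type", "layer", "fabric", "image_path")


def analyze_image(
    image: FabricImage,
    config: PipelineConfig | None = None,
) -> FabricMeasurement:
    """Measure one calibrated micrograph: coverage + interior pore sizes."""
    cfg = config or PipelineConfig()
    if image.pixel_scale is None:
        raise FabriscopeError(
            "image has no pixel scale; calibrate first or pass pixel_scale"
        )
    mask = segment(
        image,
        focus_fraction=cfg.focus_fraction,
        threshold_method=cfg.threshold_method,
        manual_value=cfg.threshold_manual_value,
        contrast_trigger_pore_fraction=cfg.contrast_auto_trigger_pore_fraction,
        contrast_percentiles=(cfg.contrast_low_pct, cfg.contrast_high_pct),
    )
    log.info(
        "analyze %s/%s region %s: threshold=%.1f contrast_adjusted=%s",
        image.mask_id,
        image.layer,
        image.region_index,
        mask.threshold_used,
        mask.contrast_adjusted,
    )
    regions = label_pores(mask, min_area_px=cfg.min_area_px)
    sizes = pore_sizes_um(regions, image.pixel_scale, k=cfg.k_pores)
    return FabricMeasurement.from_mask(mask, sizes.sizes_um, sizes.shortfall)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate the mask manifest CSV."""
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype={"mask_id": str, "layer": str})
    missing = [c for c in _MANIFEST_COLS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest is missing columns: {missing}")
    if df.empty:
        raise ManifestError("manifest lists no images")
    if "region_index" not in df.columns:
        df = df.copy()
        df["region_index"] = df.groupby(["mask_id", "layer"]).cumcount()
    return df


def run_pipeline(
    manifest: str | Path | pd.DataFrame,
    config: PipelineConfig | None = None,
    pixel_scale: float | None = None,
    out_dir: str | Path | None = None,
) -> ScreeningReport:
    """Run measurement, aggregation and ranking over a mask manifest.

    ``pixel_scale`` (um/px, e.g. from :func:`fabriscope.calibration.calibrate`)
    applies to every image; alternatively the manifest may carry a
    per-image ``pixel_scale`` column. When ``out_dir`` is given, the
    per-image measurement CSV, the per-fabric summary CSV mirroring the
    reference-table schema, and the report JSON are written there.
    """
    cfg = config or PipelineConfig()
    df = manifest if isinstance(manifest, pd.DataFrame) else read_manifest(manifest)
    if df.empty:
        raise ManifestError("manifest lists no images")

    rows: list[dict] = []
    failures: list[dict] = []
    by_fabric: dict[tuple[str, str], list[FabricMeasurement]] = {}
    fabric_info: dict[tuple[str, str], tuple[str, str]] = {}

    for rec in df.to_dict("records"):
        key = (str(rec["mask_id"]), str(rec["layer"]))
        fabric_info[key] = (str(rec["mask_type"]), str(rec.get("fabric", "")))
        scale = rec.get("pixel_scale", None)
        scale = float(scale) if scale is not None and pd.notna(scale) else pixel_scale
        try:
            image = FabricImage.from_file(
                rec["image_path"],
                pixel_scale=scale,
                mask_id=key[0],
                layer=key[1],
                region_index=int(rec["region_index"]),
            )
            m = analyze_image(image, cfg)
        except (FabriscopeError, OSError, ValueError) as exc:
            log.warning("image failed: %s (%s)", rec["image_path"], exc)
            failures.append({"image_path": str(rec["image_path"]), "error": str(exc)})
            continue
        by_fabric.setdefault(key, []).append(m)
        rows.append(
            {
                "mask_id": m.mask_id,
                "layer": m.layer,
                "region_index": m.region_index,
                "cover_factor_pct": m.cover_factor_pct,
                "porosity_pct": m.porosity_pct,
                "n_yarn": m.n_yarn,
                "n_total": m.n_total,
                "threshold_used": m.threshold_used,
                "contrast_adjusted": m.contrast_adjusted,
                "pore_sizes_um": ";".join(f"{s:.3f}" for s in m.pore_sizes_um),
            }
        )

    if not by_fabric:
        raise PipelineError("every image in the manifest failed to process")

    summaries: list[FabricSummary] = []
    for key, ms in sorted(by_fabric.items()):
        mtype, fabric = fabric_info[key]
        summaries.append(
            summarize_fabric(
                ms,
                k_pores=cfg.k_pores,
                n_regions_for_cover=cfg.n_regions_for_cover,
                mask_type=mtype,
                fabric=fabric,
            )
        )
    report = rank_fabrics(summaries, cfg.aerosol_ref_um, cfg.droplet_ref_um)

    if out_dir is not None:
        write_report(report, rows, failures, cfg, Path(out_dir))
    return report


def write_report(
    report: ScreeningReport,
    image_rows: list[dict],
    failures: list[dict],
    config: PipelineConfig,
    out_dir: Path,
) -> None:
    """Persist per-image CSV, per-fabric summary CSV, and report JSON."""
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(image_rows).to_csv(
        out_dir / "per_image.csv", index=False, float_format="%.6f"
    )
    summaries_to_frame(list(report.ranked)).to_csv(
        out_dir / "summary.csv", index=False, float_format="%.6f"
    )
    payload = {
        "recommendation": {
            "mask_id": report.recommendation[0],
            "layer": report.recommendation[1],
        },
        "reference_sizes_um": {
            "bio_aerosol": report.aerosol_ref_um,
            "respiratory_droplet_upper": report.droplet_ref_um,
        },
        "ranking": [
            {
                "rank": i + 1,
                "mask_id": s.mask_id,
                "layer": s.layer,
                "fabric": s.fabric,
                "pore_size_mean_um": s.pore_size_mean_um,
                "pore_size_sd_um": s.pore_size_sd_um,
                "cover_factor_mean_pct": s.cover_factor_mean_pct,
                "cover_factor_sd_pct": s.cover_factor_sd_pct,
                "porosity_mean_pct": s.porosity_mean_pct,
                "exceeds_aerosol_size": report.exceeds_aerosol_size[
                    (s.mask_id, s.layer)
                ],
                "exceeds_droplet_range": report.exceeds_droplet_range[
                    (s.mask_id, s.layer)
                ],
            }
            for i, s in enumerate(report.ranked)
        ],
        "failures": failures,
        "config": asdict(config),
    }
    (out_dir / "report.json").write_text(json.dumps(payload, indent=2))
    config.save(out_dir / "config.txt")
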