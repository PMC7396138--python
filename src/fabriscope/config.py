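"""Pipeline configuration: every tunable in one auditable record.

The config serializes to a flat ``key = value`` text file and round-trips
exactly, so a run can be reproduced from its saved config alone. Defaults
encode the package's standard pipeline: 0.6 focus crop, Otsu threshold
with automatic contrast stretch below a 2% pore fraction, 9-px minimum
pore area, ten pooled pore measurements and five cover-factor regions,
and the 5/100 um aerosol/droplet reference sizes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    focus_fraction: float = 0.6
    threshold_method: str = "otsu"  # "otsu" | "manual"
    threshold_manual_value: float | None = None
    contrast_auto_trigger_pore_fraction: float = 0.02
    contrast_low_pct: float = 1.0
    contrast_high_pct: float = 99.0
    min_area_px: int = 9
    k_pores: int = 10
    n_regions_for_cover: int = 5
    aerosol_ref_um: float = 5.0
    droplet_ref_um: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.focus_fraction <= 1:
            raise ValueError("focus_fraction must be in (0, 1]")
        if self.threshold_method not in ("otsu", "manual"):
            raise ValueError("threshold_method must be 'otsu' or 'manual'")
        if self.threshold_method == "manual" and self.threshold_manual_value is None:
            raise ValueError("manual thresholding requires threshold_manual_value")
        if not 0 <= self.contrast_auto_trigger_pore_fraction <= 1:
            raise ValueError("contrast trigger must be a fraction in [0, 1]")
        if not 0 <= self.contrast_low_pct < self.contrast_high_pct <= 100:
            raise ValueError("need 0 <= low_pct < high_pct <= 100")
        if self.min_area_px < 1 or self.k_pores < 1 or self.n_regions_for_cover < 1:
            raise ValueError("min_area_px, k_pores, n_regions_for_cover must be >= 1")
        if self.aerosol_ref_um <= 0 or self.droplet_ref_um <= self.aerosol_ref_um:
            raise ValueError("need 0 < aerosol_ref_um < droplet_ref_um")

    # ------------------------------------------------------- serialization

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [f"{k} = {v!r}" for k, v in asdict(self).items()]
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        values: dict[str, object] = {}
        valid = {f.name for f in fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in valid:
                raise ValueError(f"line {lineno}: unknown config key {key!r}")
            values[key] = _parse_scalar(raw.strip())
        return cls(**values)  # type: ignore[arg-type]

    def with_overrides(self, overrides: list[str]) -> "PipelineConfig":
        """Apply ``key=value`` override strings (the CLI ``--set`` flag)."""
        valid = {f.name for f in fields(self)}
        updates: dict[str, object] = {}
        for item in overrides:
            key, sep, raw = item.partition("=")
            key = key.strip()
            if not sep or key not in valid:
                raise ValueError(f"bad override {item!r}; expected key=value")
            updates[key] = _parse_scalar(raw.strip())
        return PipelineConfig(**{**asdict(self), **updates})  # type: ignore[arg-type]


def _parse_scalar(raw: str) -> object:
    if raw in ("None", ""):
        return None
    if len(raw) >= 2 and raw[0] == raw[-1] and raw[0] in "'\"":
        return raw[1:-1]
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        return raw
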