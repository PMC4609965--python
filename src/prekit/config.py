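"""Run configuration: one YAML file binding tables, sequences and constants."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .pre import RegionMap

__all__ = ["RunConfig", "TableRef", "load_run_config", "dump_run_config"]


@dataclass(frozen=True)
class TableRef:
    site: int
    arm: str
    ratio: float
    path: Path


@dataclass
class RunConfig:
    root: Path
    visible_species: str
    invisible_species: str
    sequences: dict[str, str]
    regions: dict[str, dict[str, tuple[int, int]]]  # species -> region name -> interval
    delays: list[float]
    visible_concentration: float
    ratios: list[float]
    tables: list[TableRef]
    contact_ratio: float = 1.0
    titration_site: int = 44
    noise: float | None = None
    seed: int = 0
    significance_floor: float = 8.0
    selection_threshold: float = 15.0
    selection_point: int | None = None
    aicc_margin: float = 2.0
    excluded_ratios: list[float] = field(default_factory=list)

    def region_map(self, species: str) -> RegionMap:
        return RegionMap(sequence=self.sequences[species], regions=self.regions[species])

    def table_path(self, site: int, arm: str, ratio: float) -> Path:
        for t in self.tables:
            if t.site == site and t.arm == arm and abs(t.ratio - ratio) < 1e-9:
                return t.path
        raise FileNotFoundError(
            f"no peak table registered for site {site}, arm {arm}, ratio {ratio:g}"
        )

    @property
    def sites(self) -> list[int]:
        return sorted({t.site for t in self.tables})


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    root = path.parent

    tables = []
    for entry in raw.get("tables", []):
        p = root / entry["path"]
        if not p.exists():
            raise FileNotFoundError(f"{path}: referenced table does not exist: {p}")
        tables.append(TableRef(int(entry["site"]), str(entry["arm"]), float(entry["ratio"]), p))

    ratios = [float(r) for r in raw["ratios"]]
    if ratios != sorted(ratios):
        raise ValueError(f"{path}: ratios must be sorted ascending")

    thresholds = raw.get("thresholds", {})
    floor = float(thresholds.get("significance_floor", 8.0))
    selection = float(thresholds.get("selection", 15.0))
    if floor <= 0 or selection <= 0:
        raise ValueError(f"{path}: thresholds must be positive")

    regions = {
        sp: {name: (int(a), int(b)) for name, (a, b) in intervals.items()}
        for sp, intervals in raw.get("regions", {}).items()
    }

    return RunConfig(
        root=root,
        visible_species=str(raw["visible_species"]),
        invisible_species=str(raw["invisible_species"]),
        sequences={k: str(v) for k, v in raw["sequences"].items()},
        regions=regions,
        delays=[float(t) for t in raw["delays_s"]],
        visible_concentration=float(raw["visible_concentration_M"]),
        ratios=ratios,
        tables=tables,
        contact_ratio=float(raw.get("contact_ratio", 1.0)),
        titration_site=int(raw.get("titration_site", 44)),
        noise=float(raw["noise"]) if raw.get("noise") is not None else None,
        seed=int(raw.get("seed", 0)),
        significance_floor=floor,
        selection_threshold=selection,
        selection_point=(
            int(thresholds["selection_point"])
            if thresholds.get("selection_point") is not None
            else None
        ),
        aicc_margin=float(thresholds.get("aicc_margin", 2.0)),
        excluded_ratios=[float(r) for r in raw.get("excluded_ratios", [])],
    )


def dump_run_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))
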