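"""Pipeline configuration: one flat dataclass, loadable from TOML."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .rules import RuleConfig


@dataclass
class Config:
    # grid / metric settings
    in_plane_spacing_mm: float = 1.0
    sdsc_tolerance_mm: float = 3.0
    apl_tolerance_mm: float = 0.0
    hd_percentile: float = 95.0
    # SPC estimation
    spc_alpha: float = 0.05
    spc_min_n: int = 10
    shapiro_max_n: int = 5000
    # charting
    moving_average_k: int = 30
    # ROI name aliases (raw name -> canonical name)
    roi_aliases: dict[str, str] = field(default_factory=dict)
    rules: RuleConfig = field(default_factory=RuleConfig)

    @classmethod
    def from_toml(cls, path: str | Path) -> "Config":
        data = tomllib.loads(Path(path).read_text())
        rule_data = data.pop("rules", {})
        known = {f.name for f in fields(cls)} - {"rules"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data, rules=RuleConfig(**rule_data))
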