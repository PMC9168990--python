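"""Pipeline configuration: defaults, YAML loading, and CLI overrides.

Defaults follow the acquisition/processing protocol: 0.050 mV picking
threshold, top-hat width 20 Da, export window 2450-3500 m/z, calibrant match
tolerance 1.5 Da, assignment tolerance 1.0 Da, 4 replicates, RSD bound 15%,
top-7 F-selected features, 5 CV folds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    threshold_mv: float = 0.050
    tophat_width_da: float = 20.0
    window_lo: float = 2450.0
    window_hi: float = 3500.0
    cal_match_tol: float = 1.5
    assign_tol: float = 1.0
    overlap_tol: float = 1.0
    n_replicates: int = 4
    rsd_threshold_pct: float = 15.0
    include_glycoforms: list[str] | None = None  # None = full 22 x 3 grid
    k_features: int = 7
    n_folds: int = 5
    lr: float = 0.05
    epochs: int = 2000
    l2: float = 1e-4
    seed: int = 0
    paper_mode: bool = False
    stratified: bool = True
    grouping: str = "case_control"
    extended_traits: bool = False
    fields_meta: dict = field(default_factory=dict, repr=False, compare=False)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("fields_meta", None)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
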