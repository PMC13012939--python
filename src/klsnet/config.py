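"""Pipeline configuration: YAML-backed, validated, hashable."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .atlases import METRICS


@dataclass
class EffectSection:
    affected_rois: list[list[str]] = field(default_factory=list)
    effect_size_emci: float = 0.0
    effect_size_lmci: float = 0.0
    cognition_coupling: float = 0.0
    noise_sd: float = 2.0
    samples_per_roi_mean: int = 200


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    n_cn: int = 67
    n_emci: int = 83
    n_lmci: int = 58
    metrics: list[str] = field(default_factory=lambda: ["GMV", "CT"])
    effects: dict[str, EffectSection] = field(default_factory=dict)
    # KDE
    grid_size: int = 256
    epsilon: float = 2.2e-16
    bandwidth_rule: str = "botev"
    # topology
    n_nulls: int = 100
    # stats
    fdr_alpha: float = 0.05
    # classifier
    outer_folds: int = 10
    inner_folds: int = 5
    penalty_grid_size: int = 20
    n_permutations: int = 200
    feature_panel: list[str] = field(default_factory=list)
    # stage toggles
    run_simulate: bool = True
    run_networks: bool = True
    run_topology: bool = True
    run_stats: bool = True
    run_classify: bool = True

    def __post_init__(self) -> None:
        for m in self.metrics:
            if m not in METRICS:
                raise ValueError(f"unknown metric {m!r}")
        for key in self.effects:
            if key not in METRICS:
                raise ValueError(f"effects key {key!r} is not a metric")
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if min(self.n_cn, self.n_emci, self.n_lmci) < 0:
            raise ValueError("group sizes must be >= 0")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        effects = raw.pop("effects", {}) or {}
        parsed = {}
        for metric, section in effects.items():
            eff_known = {f.name for f in fields(EffectSection)}
            bad = set(section) - eff_known
            if bad:
                raise ValueError(f"unknown effect keys for {metric}: {sorted(bad)}")
            parsed[metric] = EffectSection(**section)
        return cls(effects=parsed, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash over semantically meaningful fields (output path excluded)."""
        payload = self.to_dict()
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()
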