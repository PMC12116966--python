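"""Pipeline configuration.

A single dataclass carries every tunable threshold used across the stages:
MeRIP window geometry and enrichment cut, decay time points and stabilization
cut, DEG thresholds, and fuzzy clustering settings. Precedence is
CLI flag > YAML config file > built-in default; the built-in defaults are the
study values (100-nt window / 50-nt step / >=4-fold; FC > 1.5, p < 0.05;
|log2FC| >= 1; nine clusters; t = 0, 4, 8 h).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml


@dataclass
class PipelineConfig:
    # MeRIP peak calling
    window_nt: int = 100
    step_nt: int = 50
    min_fold: float = 4.0
    pseudo_rpkm: float = 0.5
    min_window_reads: int = 10
    # decay kinetics
    decay_timepoints: tuple[float, ...] = (0.0, 4.0, 8.0)
    ruv_k: int = 1
    ratio_cut: float = 1.5
    min_r2: float = 0.5
    # differential expression
    deg_lfc_cut: float = 1.0
    deg_fc_cut: float = 1.5
    deg_p_cut: float = 0.05
    # clustering
    cluster_count: int = 9
    fuzzifier: float = 2.0
    # spike-in identification: prefix plus optional explicit id list
    spike_prefix: str = "ERCC-"
    spike_ids: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.window_nt >= self.step_nt >= 1):
            raise ValueError("require window_nt >= step_nt >= 1")
        if self.min_fold <= 0:
            raise ValueError("min_fold must be > 0")
        for name in ("deg_lfc_cut", "deg_fc_cut", "deg_p_cut", "ratio_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.cluster_count < 1:
            raise ValueError("cluster_count must be >= 1")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier must be > 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config file, then apply keyword overrides (CLI flags).

        Overrides whose value is None are ignored so absent CLI flags fall
        through to the file value or the built-in default.
        """
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("decay_timepoints", "spike_ids"):
            if key in data and isinstance(data[key], Sequence):
                data[key] = tuple(data[key])
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def replace(self, **overrides) -> "PipelineConfig":
        clean = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **clean)
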