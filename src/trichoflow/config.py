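"""Pipeline configuration.

Every tunable of the analysis lives in :class:`PipelineConfig` so a run is
fully described by one mapping plus one seed. Defaults follow the study
design this pipeline implements: knee-calling at the 99th percentile with a
10% fraction, per-cell gene bounds 200-8000 with a UMI cap of 50 000,
marker criteria log2FC >= 0.36 / P <= 0.01 / expressed in >= 25% of the
cluster, homology e-value cutoff 1e-5, annotation weights 20/50/30 and a
non-cycling score threshold of 0.3.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # cell calling
    expected_cells: int = 1000
    knee_percentile: float = 99.0
    knee_fraction: float = 0.10
    # QC (per-cell gene-count bounds and UMI cap; the alternative profile
    # 310-6000 reported elsewhere in the study is selectable here)
    min_genes: int = 200
    max_genes: int = 8000
    max_umi: int = 50_000
    # normalization / embedding
    normalize_scale: float = 1e4
    n_top_genes: int = 2000
    n_pcs: int = 30
    regress_depth: bool = True  # remove the log-library-size axis before PCA
    # batch correction
    soft_k: int | None = None  # None -> min(100, n_cells // 30)
    sigma: float = 0.3
    diversity_strength: float = 2.0
    max_iter: int = 20
    tol: float = 1e-4
    # clustering
    n_neighbors: int = 20
    resolution: float = 1.0
    # marker detection
    log2fc_min: float = 0.36
    p_max: float = 0.01
    min_pct: float = 0.25
    # annotation
    evalue_max: float = 1e-5
    w_quantity: float = 0.20
    w_fold: float = 0.50
    w_pct: float = 0.30
    fold_saturation: float = 3.0
    min_score: float = 0.05
    # cell cycle
    noncycling_threshold: float = 0.3
    score_bins: int = 25
    score_controls: int = 50
    # trajectory
    transitional_ratio_window: tuple[float, float] = (0.5, 2.0)
    coexpr_min: float = 0.25
    n_landmarks: int = 30
    traj_n_pcs: int = 10          # components of the trajectory re-embedding
    traj_smooth_neighbors: int = 30
    traj_smooth_rounds: int = 4   # kNN-averaging rounds before landmarks
    n_trend_bins: int = 20
    n_trend_modules: int = 3
    # reproducibility
    seed: int = 0

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.w_quantity, self.w_fold, self.w_pct)

    def validate(self) -> "PipelineConfig":
        if abs(self.w_quantity + self.w_fold + self.w_pct - 1.0) > 1e-12:
            raise ValueError(
                "annotation weights must sum to 1 "
                f"(got {self.w_quantity} + {self.w_fold} + {self.w_pct})"
            )
        for name in ("w_quantity", "w_fold", "w_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.expected_cells < 1:
            raise ValueError("expected_cells must be >= 1")
        if not 0 < self.knee_percentile <= 100:
            raise ValueError("knee_percentile must lie in (0, 100]")
        if not 0 < self.knee_fraction <= 1:
            raise ValueError("knee_fraction must lie in (0, 1]")
        if self.min_genes < 0 or self.max_genes < self.min_genes:
            raise ValueError(
                f"gene bounds invalid: min_genes={self.min_genes}, "
                f"max_genes={self.max_genes}"
            )
        if self.max_umi <= 0:
            raise ValueError("max_umi must be positive")
        for name in ("normalize_scale", "sigma", "fold_saturation", "p_max",
                     "evalue_max", "resolution"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("log2fc_min", "min_pct", "noncycling_threshold",
                     "min_score", "coexpr_min", "diversity_strength"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.min_pct <= 1:
            raise ValueError("min_pct must lie in [0, 1]")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must lie in (0, 1]")
        lo, hi = self.transitional_ratio_window
        if not (0 <= lo <= hi):
            raise ValueError("transitional_ratio_window must be 0 <= lo <= hi")
        for name in ("n_top_genes", "n_pcs", "n_neighbors", "max_iter",
                     "n_landmarks", "n_trend_bins", "n_trend_modules",
                     "score_bins", "score_controls"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        return self

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["transitional_ratio_window"] = list(self.transitional_ratio_window)
        return d


_FIELD_NAMES = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(source: str | Path | Mapping[str, Any] | None = None) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig` from YAML/JSON or a mapping.

    Absent keys take the documented defaults; unknown keys are rejected.
    The three annotation weights may be given either as the flat keys
    ``w_quantity``/``w_fold``/``w_pct`` or as ``weights: [q, fold, pct]``.
    """
    if source is None:
        mapping: dict[str, Any] = {}
    elif isinstance(source, Mapping):
        mapping = dict(source)
    else:
        path = Path(source)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            mapping = json.loads(text)
        else:
            mapping = yaml.safe_load(text) or {}
        if not isinstance(mapping, dict):
            raise ValueError(f"config file {path} must contain a mapping")

    if "weights" in mapping:
        w = mapping.pop("weights")
        if len(w) != 3:
            raise ValueError("weights must have exactly three entries")
        mapping.setdefault("w_quantity", float(w[0]))
        mapping.setdefault("w_fold", float(w[1]))
        mapping.setdefault("w_pct", float(w[2]))

    unknown = set(mapping) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "transitional_ratio_window" in mapping:
        mapping["transitional_ratio_window"] = tuple(
            float(v) for v in mapping["transitional_ratio_window"]
        )
    return PipelineConfig(**mapping).validate()
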