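"""Run configuration: a single YAML file surfacing every analysis constant."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml


@dataclass
class GridConfig:
    x_min: float = 0.0
    y_min: float = 0.0
    n_cols: int = 100
    n_rows: int = 100
    cell_size: float = 2.0


@dataclass
class WorldConfig:
    grid: GridConfig = field(default_factory=GridConfig)
    n_islands: int = 3
    n_days: int = 20


@dataclass
class ColonyConfig:
    n: int = 6
    size_range: tuple[int, int] = (500, 20000)


@dataclass
class TruthConfig:
    distance_coef: float = -0.03
    peak_depth_m: float = 150.0
    width_m: float = 120.0
    amplitude: float = 2.0
    noise_sd: float = 0.5


@dataclass
class GroupConfig:
    name: str = "group_a"
    species: str = "synthetic_predator"
    vmax_ms: float = 3.0  # swimmers; flying seabirds use 20 m/s
    gap_prone: bool = False
    regularize: str = "linear"  # or "ctcrw"
    n_individuals: int = 12
    trips_per_individual: int = 4
    truth: TruthConfig = field(default_factory=TruthConfig)


@dataclass
class AnalysisConfig:
    ratio: int = 3
    accessibility_factor: float = 1.1
    fpt_radius_min_km: float = 1.0
    fpt_radius_max_km: float = 150.0
    rep_iters: int = 500
    rep_threshold: float = 75.0
    isopleth_level: float = 0.5
    knots: int = 3
    vif_threshold: float = 3.0
    tie_epsilon: float = 0.01
    presence_threshold: float = 0.5
    return_radius_km: float = 2.0
    min_trip_fixes: int = 3
    gap_mean_speed_kmh: float = 6.0
    fallback_h_km: float = 10.0


@dataclass
class ErrorModelConfig:
    argos_sd: float = 1.0
    gap_prob: float = 0.05
    fastloc_sat_range: tuple[int, int] = (3, 12)


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "out"
    world: WorldConfig = field(default_factory=WorldConfig)
    colonies: ColonyConfig = field(default_factory=ColonyConfig)
    groups: list[GroupConfig] = field(default_factory=lambda: [GroupConfig()])
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    error_model: ErrorModelConfig = field(default_factory=ErrorModelConfig)

    def validate(self) -> None:
        problems = []
        a = self.analysis
        if a.ratio < 1:
            problems.append("analysis.ratio must be >= 1")
        if a.accessibility_factor <= 0:
            problems.append("analysis.accessibility_factor must be positive")
        if not 0 < a.isopleth_level < 1:
            problems.append("analysis.isopleth_level must be in (0,1)")
        if a.knots < 3:
            problems.append("analysis.knots must be >= 3")
        if a.rep_iters < 1 or a.rep_threshold <= 0:
            problems.append("representativeness settings must be positive")
        if not self.groups:
            problems.append("at least one group is required")
        for g in self.groups:
            if g.vmax_ms <= 0:
                problems.append(f"group {g.name}: vmax must be positive")
            if g.truth.distance_coef >= 0:
                problems.append(f"group {g.name}: truth.distance_coef must be negative")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))

    def fpt_radii(self) -> np.ndarray:
        a = self.analysis
        lo, hi = a.fpt_radius_min_km, a.fpt_radius_max_km
        near = np.arange(lo, min(30.0, hi), 2.0)
        far = np.arange(30.0, hi + 1e-9, 10.0)
        return np.unique(np.concatenate([near, far, [hi]]))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _from_dict(cls, d):
    if d is None:
        return cls()
    kwargs = {}
    for name, f in cls.__dataclass_fields__.items():
        if name not in d:
            continue
        v = d[name]
        sub = {"grid": GridConfig, "truth": TruthConfig, "world": WorldConfig,
               "colonies": ColonyConfig, "analysis": AnalysisConfig,
               "error_model": ErrorModelConfig}.get(name)
        if sub is not None and isinstance(v, dict):
            v = _from_dict(sub, v)
        elif name == "groups":
            v = [_from_dict(GroupConfig, g) for g in v]
        elif name in ("size_range", "fastloc_sat_range"):
            v = tuple(v)
        kwargs[name] = v
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _from_dict(RunConfig, data)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
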