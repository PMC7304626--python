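"""Run configuration: model constants, fitting hyperparameters, seeds.

All constants carry units in their field docs.  The cardinal temperatures and
photoperiods of the developmental-rate model and the crop-growth-model
constants are fixed across lines; everything else is tunable per run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class DVRCardinals:
    """Fixed cardinal points of the developmental-rate response functions.

    Temperatures in °C (base / optimum / ceiling), photoperiods in hours.
    """

    t_b: float = 8.0
    t_o: float = 30.0
    t_c: float = 42.0
    p_b: float = 0.0
    p_o: float = 10.0
    p_c: float = 24.0

    def __post_init__(self) -> None:
        if not (self.t_b < self.t_o < self.t_c):
            raise ValueError("cardinal temperatures must satisfy t_b < t_o < t_c")
        if not (self.p_b < self.p_o < self.p_c):
            raise ValueError("cardinal photoperiods must satisfy p_b < p_o < p_c")


@dataclass(frozen=True)
class CGMConstants:
    """Crop-growth-model constants.

    irue: maximum radiation-use efficiency, g biomass per MJ intercepted PAR.
    k: canopy light-extinction coefficient (dimensionless).
    beta_leaf: leaf-shape coefficient converting (length)² to leaf area.
    s_ground: ground area of one plant, m² (225 cm²).
    seed_growth_degree_days: post-heading degree-day sum (°C·d) terminating
        seed growth (TSG).
    tiller_hu_threshold: heat units (°C·d) below which tiller count is 1.
    """

    irue: float = 2.2
    k: float = 0.6
    beta_leaf: float = 0.003
    s_ground: float = 0.0225
    seed_growth_degree_days: float = 630.0
    tiller_hu_threshold: float = 800.0

    def __post_init__(self) -> None:
        for name in ("irue", "k", "beta_leaf", "s_ground",
                     "seed_growth_degree_days", "tiller_hu_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class PSOSettings:
    """Particle-swarm hyperparameters for fitting (α, β_P, G) per line."""

    swarm_size: int = 50
    iterations: int = 200
    inertia: float = 0.7
    c1: float = 1.5
    c2: float = 1.5
    alpha_bounds: tuple[float, float] = (0.0, 10.0)
    beta_bounds: tuple[float, float] = (0.0, 15.0)
    g_bounds: tuple[float, float] = (40.0, 200.0)
    retry_cap: int = 3


@dataclass(frozen=True)
class ELMSettings:
    """Extreme-learning-machine settings for the genotype→parameter map."""

    hidden_nodes: int = 50
    ridge: float = 1e-3

    def __post_init__(self) -> None:
        if self.hidden_nodes < 1:
            raise ValueError("hidden_nodes must be >= 1")


@dataclass(frozen=True)
class GPSettings:
    """Genomic-prediction defaults: method and internal CV folds for tuning."""

    method: str = "lasso"
    cv_folds: int = 5


@dataclass(frozen=True)
class CVSettings:
    """Cross-validation among genotypes: fold count and replicate count."""

    k: int = 10
    replicates: int = 100


@dataclass
class Config:
    """Top-level run configuration.

    latitude: degrees north, per environment id.
    heat_unit_mode: 'simple' (∑T) or 'base8' (∑max(0, T−8)).
    twilight_angle: solar elevation (degrees) defining day length;
        −0.833° is geometric sunrise/sunset with standard refraction.
    emergence_offset_days: days added to sowing date to get the
        developmental origin (emergence).
    """

    cgm: CGMConstants = field(default_factory=CGMConstants)
    dvr: DVRCardinals = field(default_factory=DVRCardinals)
    gp: GPSettings = field(default_factory=GPSettings)
    pso: PSOSettings = field(default_factory=PSOSettings)
    elm: ELMSettings = field(default_factory=ELMSettings)
    cv: CVSettings = field(default_factory=CVSettings)
    seed: int = 0
    latitude: dict[str, float] = field(default_factory=dict)
    heat_unit_mode: str = "simple"
    twilight_angle: float = -0.833
    emergence_offset_days: int = 0

    def __post_init__(self) -> None:
        if self.heat_unit_mode not in ("simple", "base8"):
            raise ValueError("heat_unit_mode must be 'simple' or 'base8'")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Config":
        d = dict(d)
        for key, sub in (("cgm", CGMConstants), ("dvr", DVRCardinals),
                         ("gp", GPSettings), ("pso", PSOSettings),
                         ("elm", ELMSettings), ("cv", CVSettings)):
            if key in d and isinstance(d[key], dict):
                sub_d = dict(d[key])
                for bkey in ("alpha_bounds", "beta_bounds", "g_bounds"):
                    if bkey in sub_d and isinstance(sub_d[bkey], list):
                        sub_d[bkey] = tuple(sub_d[bkey])
                d[key] = sub(**sub_d)
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, default=str))
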