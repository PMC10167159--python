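"""Structured YAML run configuration.

Schema (all blocks optional; keys mirror the parameter dataclasses)::

    geometric:
      power_law_exponent: 3.0
      allometric_exponent: 1.0
      r_min: 0.05            # cm
      q_min: 0.01            # ml/s
      l_min: 4.0             # cm
      source_distance_criterion: 2.0
    optimization:
      viscosity_mu: 0.04                 # poise
      metabolic_coefficient_beta: null   # null = self-consistent default
    growth:
      growth_step: null      # cm; null derives from the mesh
      n_workers: 1
      refine_3d: true
    flow1d:
      blood_density: 1.06
      kinematic_viscosity: 0.0377
      delta: 0.3333333333
    darcy:
      mobility: 0.000107     # 1/(mmHg s)
    coupling:
      pressure_tolerance: 1.0e-6
      flow_tolerance: 1.0e-8
      max_iterations: 200
      beta_sink_adjustment_bound: 0.02
      relaxation: 0.5
      inlet_pressure: 100.0

Unknown keys raise a ConfigError naming the offending key.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from vasgrow.vascular_forest import GeometricParams, OptimizationParams
from vasgrow.flow1d import FlowParams1D
from vasgrow.darcy_perfusion import DarcyParams
from vasgrow.coupled_driver import CouplingConfig


class ConfigError(ValueError):
    pass


@dataclass
class GrowthConfig:
    growth_step: float | None = None
    n_workers: int = 1
    refine_3d: bool = True


@dataclass
class RunConfig:
    geometric: GeometricParams = field(default_factory=GeometricParams)
    optimization: OptimizationParams = field(default_factory=OptimizationParams)
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    flow1d: FlowParams1D = field(default_factory=FlowParams1D)
    darcy: DarcyParams = field(default_factory=DarcyParams)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)


_BLOCKS = {
    "geometric": GeometricParams,
    "optimization": OptimizationParams,
    "growth": GrowthConfig,
    "flow1d": FlowParams1D,
    "darcy": DarcyParams,
    "coupling": CouplingConfig,
}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    cfg = RunConfig()
    for block, content in raw.items():
        if block not in _BLOCKS:
            raise ConfigError(f"{path}: unknown config block {block!r}")
        cls = _BLOCKS[block]
        names = {f.name for f in dataclasses.fields(cls)}
        content = content or {}
        for key in content:
            if key not in names:
                raise ConfigError(f"{path}: unknown key {block}.{key}")
        try:
            setattr(cfg, block, cls(**content))
        except (TypeError, ValueError) as e:
            raise ConfigError(f"{path}: invalid {block} block: {e}") from e
    return cfg
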