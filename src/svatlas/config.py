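"""Pipeline configuration: strict YAML schema with the method's constants.

All method parameters live here as defaults (temporal kernel sigma 0.7
months, age-window half-width 1.5 months, corrective-displacement delta 6 mm
and sigma_g 3 mm, solver weights) and are never hard-coded at call sites.
Unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class ScdemConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha: float = Field(0.15, ge=0)
    beta: float = Field(8.0, ge=0)
    gamma: float = Field(1.0, ge=0)
    dt: float | None = Field(None, gt=0)
    damping: float = Field(0.25, ge=0, lt=1)
    max_steps: int = Field(150, ge=1)
    force_tol: float = Field(1e-4, gt=0)
    surface_kernel_mm: float | None = Field(None, gt=0)

    def to_params(self):
        from .scdem import ScdemParams

        return ScdemParams(**self.model_dump())


class SphereRegConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_levels: int = Field(3, ge=1)
    step: float = Field(0.1, gt=0)
    smooth_sigma: float = Field(2.0, gt=0)
    max_iter_per_level: int = Field(60, ge=1)
    correspondences: str | None = None  # CSV path bypassing registration


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_subjects: int = Field(12, ge=1)
    grid_n: int = Field(48, ge=16)
    grid_spacing_mm: float = Field(2.0, gt=0)
    noise_sd: float = Field(3.0, ge=0)
    mesh_subdivisions: int = Field(3, ge=1)


class TrajectoryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    k: int = Field(8, ge=4)
    year1_start: float = Field(0.5, ge=0)  # baseline of the first-year change
    year1_end: float = Field(12.0, gt=0)
    year2_end: float = Field(24.0, gt=0)
    velocity_grid_step: float = Field(0.1, gt=0)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cohort_dir: str = "cohort"
    out_dir: str = "out"
    window_half_width: float = Field(1.5, gt=0)
    kernel_sigma: float = Field(0.7, gt=0)
    reference_age: float = Field(12.0, gt=0)
    corrective_delta_mm: float = Field(6.0, gt=0)
    corrective_sigma_g_mm: float = Field(3.0, gt=0)
    groupwise_rounds: int = Field(1, ge=0)
    months: list[float] = Field(default_factory=lambda: [0.5] + [float(m) for m in range(1, 25)])
    seed: int = 0
    scdem: ScdemConfig = Field(default_factory=ScdemConfig)
    sphere: SphereRegConfig = Field(default_factory=SphereRegConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    trajectories: TrajectoryConfig = Field(default_factory=TrajectoryConfig)

    @field_validator("months")
    @classmethod
    def _months_in_range(cls, v):
        for m in v:
            if not (0.0 <= m <= 36.0):
                raise ValueError(f"month {m} outside [0, 36]")
        return v

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        if not isinstance(data, dict):
            raise ValueError("config must be a YAML mapping")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.model_dump(), f, sort_keys=False)
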