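"""Experiment configuration: a validated, defaulted YAML schema.

One :class:`ExperimentConfig` fully determines a pipeline run (simulation
grid, preprocessing, model, training, LASCA settings) given the master seed;
unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .conditions import FlowCondition

__all__ = ["ExperimentConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    """Which (diameter, depth) cells to simulate and how."""

    diameters_mm: list[float] = [3.0, 6.0]
    depths_mm: dict[float, list[float]] = {3.0: [0.0, 5.0, 10.0], 6.0: [0.0, 5.0]}
    replicates: int = Field(3, ge=1)
    velocity_sampling: str = "uniform"

    @field_validator("velocity_sampling")
    @classmethod
    def _check_sampling(cls, v):
        if v not in ("uniform", "midpoint"):
            raise ValueError(f"velocity_sampling must be uniform|midpoint, got {v!r}")
        return v

    def cells(self) -> list[tuple[float, float]]:
        return [(d, z) for d in self.diameters_mm for z in self.depths_mm[d]]


class SimOverrides(_Strict):
    """Overrides applied on top of the desk- or full-scale parameter profile."""

    profile: str = "desk"  # desk | full
    height: Optional[int] = None
    width: Optional[int] = None
    fps: Optional[float] = None
    duration: Optional[float] = None
    grain_radius: Optional[float] = None
    pulse_modulation: Optional[float] = None
    decorrelation_scale: Optional[float] = None
    exposure_substeps: Optional[int] = None
    translation_amplitude: Optional[float] = None
    noise_sigma: Optional[float] = None

    @field_validator("profile")
    @classmethod
    def _check_profile(cls, v):
        if v not in ("desk", "full"):
            raise ValueError(f"profile must be desk|full, got {v!r}")
        return v

    def overrides(self) -> dict:
        return {
            k: v
            for k, v in self.model_dump().items()
            if k != "profile" and v is not None
        }


class PreprocessConfig(_Strict):
    chunk_size: int = Field(64, ge=1)
    chunk_stride: int = Field(32, ge=1)


class ModelSection(_Strict):
    profile: str = "desk"  # desk | full
    n_classes: int = Field(4, ge=2)

    @field_validator("profile")
    @classmethod
    def _check_profile(cls, v):
        if v not in ("desk", "full"):
            raise ValueError(f"profile must be desk|full, got {v!r}")
        return v


class TrainSection(_Strict):
    batch_size: int = Field(8, ge=1)
    epochs: int = Field(20, ge=0)
    learning_rate: float = Field(1e-3, gt=0)
    half_precision: bool = False


class LascaConfig(_Strict):
    window: int = Field(7, ge=3)
    calibration_depth_mm: float = 10.0
    test_depths_mm: list[float] = [10.0, 5.0]
    condition: str = "MEDIUM"

    @field_validator("window")
    @classmethod
    def _check_window(cls, v):
        if v % 2 == 0:
            raise ValueError("window must be odd")
        return v

    @field_validator("condition")
    @classmethod
    def _check_condition(cls, v):
        if v not in FlowCondition.__members__:
            raise ValueError(f"unknown condition {v!r}")
        return v


class ExperimentConfig(_Strict):
    """Top-level configuration; only ``seed`` is required."""

    seed: int
    output_dir: str = "speckleflow_run"
    grid: GridConfig = GridConfig()
    simulation: SimOverrides = SimOverrides()
    preprocessing: PreprocessConfig = PreprocessConfig()
    model: ModelSection = ModelSection()
    training: TrainSection = TrainSection()
    lasca: LascaConfig = LascaConfig()

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


def load_config(path) -> ExperimentConfig:
    """Parse, default and validate a YAML config file; unknown keys error."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text()) or {}
    return ExperimentConfig(**data)


def save_config(config: ExperimentConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(config.to_yaml())
    return path
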