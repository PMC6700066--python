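"""Versioned YAML pipeline configuration with strict schema validation.

Unknown keys are rejected so a typo fails loudly before any stage runs.  The
single global seed fans out to per-stage seeds through
:func:`semsr.pipeline.stage_seed`, giving stage-level reproducibility without
seed collisions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Strict):
    n_train_fields: int = 8
    n_test_fields: int = 4
    field_px: int = 256
    hr_pixel_nm: float = 7.1
    n_particles: int = 24
    near_pair_fraction: float = 1.0
    radius_range_nm: tuple[float, float] = (14.0, 45.0)
    gap_range_nm: tuple[float, float] = (6.0, 28.0)
    gt_psf_nm: float = 2.0
    lr_psf_nm: float = 8.0
    downsample_factor: int = 2
    noise_poisson_scale: float = 5e-4
    noise_gaussian_sigma: float = 0.015
    damage_magnitude_px: float = 0.0     # warp the ground truth to emulate beam damage
    damage_smoothness_px: float = 64.0


class RegisterSection(_Strict):
    mode: Literal["none", "affine", "elastic"] = "none"
    levels: int = 3
    min_block_px: int = 24
    upsample_factor: int = 2


class PrepareSection(_Strict):
    patch_size: int = 32
    stride: int | None = None
    filter_threshold: float = 0.5


class TrainSection(_Strict):
    iterations: int = 600
    d_update_period: int = 4
    batch_size: int = 4
    learning_rate: float = 1e-3
    depth: int = 2
    base_channels: int = 8
    leaky_slope: float = 0.2
    upsampling: Literal["resize-conv", "transposed-conv"] = "resize-conv"
    d_blocks: int = 3
    d_base_channels: int = 8
    alpha: float | None = 2e-5   # None -> calibrate on a warm-up batch
    beta: float | None = 2e-3


class EvaluateSection(_Strict):
    exist_frac: float = 0.6
    width_frac: float = 0.8
    n_spectrum_bins: int = 64


import warnings as _warnings

with _warnings.catch_warnings():
    # the "register" stage section intentionally reuses a BaseModel attribute name
    _warnings.filterwarnings("ignore", message='Field name "register"')

    class PipelineConfig(_Strict):
        version: int = 1
        seed: int = 0
        out_dir: str = "semsr_out"
        verbosity: int = 1
        simulate: SimulateSection = Field(default_factory=SimulateSection)
        register: RegisterSection = Field(default_factory=RegisterSection)
        prepare: PrepareSection = Field(default_factory=PrepareSection)
        train: TrainSection = Field(default_factory=TrainSection)
        evaluate: EvaluateSection = Field(default_factory=EvaluateSection)

        @classmethod
        def from_yaml(cls, path: str | Path) -> "PipelineConfig":
            data = yaml.safe_load(Path(path).read_text()) or {}
            return cls.model_validate(data)

        def to_yaml(self, path: str | Path) -> None:
            Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
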