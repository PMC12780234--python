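"""Run configuration: every pipeline constant surfaced as a named default.

The defaults collect the constants the analysis pipeline is built around —
the 0.6 x 0.6 x 6.0 mm grid, the 384 x 384 x 24 training patch, the 1:1
focal/Dice loss, the 0.01 detection IoU threshold, the 5 mm severity cut
and the 0.5 adhesion decision threshold — so nothing lives as a buried
literal.  Configurations load from YAML with schema validation.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .volume_io import DEFAULT_PATCH_SHAPE, DEFAULT_SPACING

__all__ = ["RunConfig", "load_config"]


class LossSettings(BaseModel):
    focal_gamma: float = Field(2.0, ge=0)
    focal_weight: float = Field(1.0, gt=0)
    dice_weight: float = Field(1.0, gt=0)
    use_boundary: bool = False
    boundary_weight: float = 1.0


class AugmentationSettings(BaseModel):
    zoom_range: tuple[float, float] = (0.9, 1.2)
    intensity_shift_range: tuple[float, float] = (-0.1, 0.1)
    noise_sd: float = Field(0.1, ge=0)
    histogram_warp_strength: float = Field(0.3, ge=0)


class PhantomSettings(BaseModel):
    image_shape: tuple[int, int, int] = (128, 128, 16)
    t1_shape: tuple[int, int, int] = (96, 96, 12)
    noise_sd: float = Field(0.05, ge=0)


class RunConfig(BaseModel):
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING
    patch_shape: tuple[int, int, int] = DEFAULT_PATCH_SHAPE
    sliding_window_overlap: float = Field(0.5, ge=0, lt=1)
    loss: LossSettings = LossSettings()
    augmentation: AugmentationSettings = AugmentationSettings()
    phantom: PhantomSettings = PhantomSettings()
    cv_folds: int = Field(5, ge=2)
    seed: int = 0
    iou_threshold: float = Field(0.01, gt=0, le=1)
    severity_threshold_mm: float = Field(5.0, gt=0)
    decision_threshold: float = Field(0.5, gt=0, lt=1)

    @field_validator("spacing_mm")
    @classmethod
    def _positive_spacing(cls, v):
        if any(s <= 0 for s in v):
            raise ValueError("spacing must be strictly positive")
        return v


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; ``None`` gives the defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
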