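"""Validated pipeline configuration (YAML-backed).

Unknown keys are rejected everywhere so a typo in a config file fails fast
instead of silently running with defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SegmentationParams(_Strict):
    smooth_sigma_px: float = 2.0
    min_area_px: int = 500
    nucleus_min_area_px: int = 20
    hessian_sigmas: list[float] = Field(default_factory=lambda: [1.0, 2.0, 4.0])


class YapParams(_Strict):
    background: float | None = None
    background_dilate_px: int = 10
    e_min: float = 2.0
    p_min_um: float = 5.0
    measure_lengths: bool = False


class FiberParams(_Strict):
    channel: str = "collagen"
    sigma_grad_px: float = 1.0
    sigma_window_px: float = 4.0
    roi_spacing_um: float = 30.0
    roi_width_um: float = 30.0
    roi_length_um: float = 50.0
    max_distance_um: float = 50.0
    weight_by_coherency: bool = True
    coherency_power: float = 2.0


class MorphParams(_Strict):
    blur_sigma_px: float = 2.0
    erosion_iter: int = 2


class BeadParams(_Strict):
    mode: str = "diameter"
    max_step_px: float | None = None
    spot_sigma_px: float = 1.5
    threshold_rel: float = 0.5
    frame_interval_min: float | None = None


class PipelineConfig(_Strict):
    """Top-level run configuration; stages run only when their input is set."""

    image: str | None = None  # multichannel TIFF for segment/yap/fibers
    stack: str | None = None  # time-lapse TIFF for beads
    border_mask: str | None = None  # mask for the protrusive index
    channels: dict[str, str] = Field(  # file channel name -> canonical name
        default_factory=lambda: {"DAPI": "DAPI", "K8": "K8", "K14": "K14", "Yap": "Yap"}
    )
    pixel_size_um: float | None = None
    output_dir: str = "mechanoquant_out"
    seed: int = 0
    image_id: str = "image0"
    segmentation: SegmentationParams = Field(default_factory=SegmentationParams)
    yap: YapParams = Field(default_factory=YapParams)
    fibers: FiberParams = Field(default_factory=FiberParams)
    morph: MorphParams = Field(default_factory=MorphParams)
    beads: BeadParams = Field(default_factory=BeadParams)

    @field_validator("pixel_size_um")
    @classmethod
    def _positive_px(cls, v):
        if v is not None and v <= 0:
            raise ValueError("pixel_size_um must be positive")
        return v

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (where outputs go is excluded)."""
        payload = self.model_dump()
        payload.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def ensure_output_dir(self) -> Path:
        out = Path(self.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out
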