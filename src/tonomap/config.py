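"""Pipeline configuration.

Every constant of the analysis (threshold fraction, upsampling factors,
angular bin widths, deconvolution width, gridline limits, rotation angle)
is a configuration default here — nothing is hard-coded in the stages —
so a run is fully described by its config echo.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .synthetic import CohortSpec


class ProcessingConfig(BaseModel):
    threshold_frac: float = Field(0.6, gt=0, lt=1)
    upsample_factor: int = Field(50, ge=1)
    d_theta_deg: float = 0.05
    downsample_factor: int = 100
    k_intermediates: int = 4
    rl_iterations: int = Field(10, ge=1)
    psf_width_um: float = Field(200.0, ge=0)
    width_is_fwhm: bool = True
    smooth_before_deconvolve: bool = True
    smooth_size: int = 5
    response_window_frames: int = 5
    search_halfwidth_mm: float = 0.45
    trim_halfwidth_mm: float = 0.30
    connectivity: int = 2
    resample_deg: float = 2.5


class InjectionConfig(BaseModel):
    measurement_sd_mm: float = Field(0.2, ge=0)
    snap: bool = True
    snap_step_mm: float = 0.02


class AtlasConfig(BaseModel):
    rc_start_mm: float = 2.0
    rc_end_mm: float = 4.0
    step_mm: float = 0.2
    decimals: int = 2
    rotation_deg: float = 15.0
    render_overlays: bool = False


class PipelineConfig(BaseModel):
    """Full parameter set of one end-to-end run."""

    cohort: CohortSpec = Field(default_factory=CohortSpec)
    processing: ProcessingConfig = Field(default_factory=ProcessingConfig)
    injection: InjectionConfig = Field(default_factory=InjectionConfig)
    atlas: AtlasConfig = Field(default_factory=AtlasConfig)
    truth_radius_mm: float = 0.15
    truth_amplitude: float = 0.02
    save_stacks: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False))
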