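"""Pipeline configuration: one validated structure holding every constant.

Defaults are the values used for the DRG/Dm MT analyses: 8-nm dimer picking,
28-degree in-plane and 2.2-nm axial alignment limits, 80% per-MT
cross-correlation retention, the strict >70% polarity vote, >95% automatic
pf assignment with the >20-particle transition patch, 3.5-nm/25-degree
distance cleaning, 27.69-degree/0.92-nm 13-pf helical expansion, and
5-nm/>=2-particle cluster cleaning for luminal particles.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["PipelineConfig", "load_config", "save_config"]


class SceneConfig(BaseModel):
    n_mts: int = 2
    mt_length_nm: float = 300.0
    pf_number: int = 13
    wall_radius_nm: float = 10.6
    mip_rate_per_um: float = 72.0
    snr: float | None = 0.5
    tilt_range_deg: float = 60.0
    voxel_nm: float = 1.0


class PickingConfig(BaseModel):
    spacing_nm: float = 8.0  # tubulin dimer; 4 nm = monomer
    box_size: int = 33

    @field_validator("box_size")
    @classmethod
    def _odd(cls, v):
        if v % 2 == 0:
            raise ValueError("box_size must be odd")
        return v


class AlignConfig(BaseModel):
    max_inplane_deg: float = 28.0
    max_axial_shift_nm: float = 2.2
    max_lateral_shift_nm: float = 0.0
    helical_rot_deg: float = 27.69
    helical_rise_nm: float = 0.92
    helical_copies: int = 12
    distance_clean_nm: float = 3.5
    distance_clean_deg: float = 25.0


class ClassifyConfig(BaseModel):
    polarity_threshold: float = 0.70
    cc_clean_fraction: float = 0.80
    pf_auto_threshold: float = 0.95
    transition_min_patch: int = 20
    n_eigenvectors: int = 40
    eigenvector_scan_top: int = 20
    mra_rounds_pf: int = 3
    mra_rounds_polarity: int = 1

    @field_validator("polarity_threshold", "cc_clean_fraction", "pf_auto_threshold")
    @classmethod
    def _unit_interval(cls, v):
        if not 0 < v <= 1:
            raise ValueError("thresholds must lie in (0, 1]")
        return v


class MipConfig(BaseModel):
    cluster_radius_nm: float = 5.0
    cluster_min_size: int = 2
    search_cluster_radius_nm: float = 7.0
    search_cluster_min_size: int = 6
    lumen_radius_nm: float = 4.0
    adjacent_window_nm: float = 100.0
    cc_threshold: float = 0.03


class PipelineConfig(BaseModel):
    scene: SceneConfig = Field(default_factory=SceneConfig)
    picking: PickingConfig = Field(default_factory=PickingConfig)
    align: AlignConfig = Field(default_factory=AlignConfig)
    classify: ClassifyConfig = Field(default_factory=ClassifyConfig)
    mips: MipConfig = Field(default_factory=MipConfig)
    seed: int = 0
    output_dir: str = "axontomo_out"

    def config_hash(self) -> str:
        import hashlib
        import json

        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(data)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
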