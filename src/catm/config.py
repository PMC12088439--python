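"""Validated configuration for the pipeline.

Every tunable default of the package lives in one schema
(:class:`PipelineConfig`), loadable from YAML with pydantic validation, so
a run is fully described by (config, seed).
"""

from __future__ import annotations

import hashlib
import json

import yaml
from pydantic import BaseModel, Field, model_validator


class ImagingConfig(BaseModel):
    tilt_min: float = -60.0
    tilt_max: float = 60.0
    ctf_defocus_um: float = 4.0
    ctf_voltage_kv: float = 300.0
    ctf_cs_mm: float = 2.7
    ctf_amplitude_contrast: float = Field(0.07, ge=0.0, le=1.0)
    snr: float = Field(0.078, gt=0.0)
    noise_correlation_nm: float = Field(1.0, ge=0.0)

    @model_validator(mode="after")
    def _tilts(self):
        if not -90.0 <= self.tilt_min < self.tilt_max <= 90.0:
            raise ValueError("require -90 <= tilt_min < tilt_max <= 90")
        return self


class SimulationSettings(BaseModel):
    box_size_nm: float = Field(128.0, gt=0)
    voxel_size_nm: float = Field(1.0, gt=0)
    n_nucleosomes: int = Field(150, ge=0)
    n_dna: int = Field(50, ge=0)


class TemplateConfig(BaseModel):
    diameter_nm: float = Field(11.0, gt=0)
    height_nm: float = Field(5.5, gt=0)
    dna_diameter_nm: float = Field(2.0, gt=0)
    dna_length_nm: float = Field(10.0, gt=0)
    mask_threshold_fraction: float = Field(0.5, gt=0, lt=1)


class TmConfig(BaseModel):
    angular_step_deg: float = Field(15.0, gt=0)
    nms_cutoff_nm: float = Field(4.0, gt=0)
    score_floor: float = 0.1
    threshold_sweep_start: float = 0.05
    threshold_sweep_stop: float = 0.9
    threshold_sweep_step: float = 0.02


class CatmSettings(BaseModel):
    angular_step_deg: float = Field(10.0, gt=0)
    search_radius_nm: float = Field(5.0, ge=0)
    retain_threshold: float = 0.3
    clash_tolerance_fraction: float = Field(0.05, ge=0, lt=1)
    lowpass_sigma_nm: float = Field(0.0, ge=0)
    mask_dilation_voxels: int = Field(4, ge=0)
    centroid_source: str = "segmentation"  # or "matched_filter"
    centroid_jitter_nm: float = 1.5
    centroid_miss_rate: float = 0.02
    centroid_extra_rate: float = 0.02


class EvalConfig(BaseModel):
    dist_tol_nm: float = Field(5.5, gt=0)
    ang_tol_deg: float = Field(20.0, gt=0)


class AnalysisConfig(BaseModel):
    gap_threshold_nm: float = Field(1.0, gt=0)
    center_threshold_nm: float = Field(12.0, gt=0)
    dbscan_eps_nm: float = Field(12.0, gt=0)
    dbscan_min_pts: int = Field(3, ge=1)
    depth_bin_width_nm: float = Field(10.0, gt=0)
    boundary_margin_nm: float = Field(20.0, ge=0)


class PipelineConfig(BaseModel):
    """All tunables of simulation, matching, assignment and analysis."""

    imaging: ImagingConfig = ImagingConfig()
    simulation: SimulationSettings = SimulationSettings()
    template: TemplateConfig = TemplateConfig()
    tm: TmConfig = TmConfig()
    catm: CatmSettings = CatmSettings()
    evaluation: EvalConfig = EvalConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    n_tomograms: int = Field(3, ge=1)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
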