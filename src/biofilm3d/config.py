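"""Pipeline configuration: validated models, YAML round-trip, seed fan-out.

Configuration is YAML on disk and pydantic in memory; the published JSON
schema is ``PipelineConfig.model_json_schema()``.  All literature-derived
constants surface here as defaults (interior/membrane confidence thresholds
0.94/0.88, CV cutoff ρ = 1.1, dilation 1 voxel, 64×64×8 density tiles, IoU
matching threshold 0.5) rather than being hard-coded in the pipeline.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .arrangement import GrowthParams, SPECIES_PRESETS
from .postprocess import CVFilterParams, LCutsParams, SegmentationConfig, expected_cell_volume

__all__ = [
    "ArrangementConfig",
    "ImagingConfig",
    "SegmentationSettings",
    "EvaluationConfig",
    "PipelineConfig",
    "stage_seed",
]


def stage_seed(master_seed: int, stage: int) -> int:
    """Derive an independent per-stage seed from one master seed.

    Counter-based fan-out through numpy's SeedSequence, so any stage can be
    re-run in isolation; results stay below 2**31.
    """
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, int(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


class ArrangementConfig(BaseModel):
    species: Literal["e_coli", "m_xanthus", "s_aureus"] = "e_coli"
    diameter_um: Optional[float] = Field(None, gt=0)
    division_length_um: Optional[float] = Field(None, gt=0)
    max_cells: int = Field(300, ge=1)
    elongation_rate_um: float = Field(0.2, gt=0)
    target_density: Optional[float] = Field(0.6, gt=0, lt=1)
    density_tile_shape: tuple[int, int, int] = (8, 64, 64)
    # fraction of cells replaced by a second population (spherical by default)
    population2_fraction: float = Field(0.0, ge=0, le=1)
    population2_shape_um: tuple[float, float] = (1.0, 0.0)  # (diameter, cyl length)

    def growth_params(self) -> GrowthParams:
        import dataclasses

        base = SPECIES_PRESETS[self.species]
        kwargs = {"max_cells": self.max_cells, "elongation_rate": self.elongation_rate_um}
        if self.diameter_um is not None:
            kwargs["diameter"] = self.diameter_um
        if self.division_length_um is not None:
            kwargs["division_length"] = self.division_length_um
        return dataclasses.replace(base, **kwargs)


class ImagingConfig(BaseModel):
    labeling: Literal["interior", "membrane", "both"] = "interior"
    emitters_per_cell: tuple[int, int] = (500, 1000)
    photons_per_emitter: float = Field(1.0, gt=0)
    background_photons: float = Field(200.0, ge=0)
    read_noise_sd: float = Field(3.04, ge=0)
    target_sbr: float = Field(1.34, gt=1)
    psf_fwhm_lateral_um: float = Field(0.23, gt=0)
    psf_fwhm_axial_um: float = Field(0.57, gt=0)
    psf_path: Optional[str] = None
    deconvolve: bool = True
    rl_iterations: int = Field(10, ge=1)
    background_percentile: float = Field(20.0, gt=0, lt=100)
    # surrogate confidence generator (stands in for CNN inference)
    surrogate_blur_sd: float = Field(1.0, ge=0)
    surrogate_flip_noise: float = Field(0.0, ge=0, lt=1)
    surrogate_sharpness: float = Field(3.0, gt=0)

    @model_validator(mode="after")
    def _check_emitters(self):
        lo, hi = self.emitters_per_cell
        if not 0 < lo <= hi:
            raise ValueError("emitters_per_cell must satisfy 0 < min <= max")
        return self


class SegmentationSettings(BaseModel):
    tau: Optional[float] = Field(None, gt=0, lt=1)  # default follows labeling mode
    min_volume_fraction: float = Field(0.1, gt=0, lt=1)
    dilation_radius: Literal[1, 2] = 1
    rho: float = Field(1.1, gt=0)
    min_size_fraction: float = Field(0.25, gt=0, lt=1)
    expected_diameter_um: float = Field(1.0, gt=0)
    expected_length_um: float = Field(3.0, gt=0)
    sigma_d_um: float = Field(1.0, gt=0)
    sigma_t: float = Field(0.3, gt=0)
    r_um2: float = Field(2.25, gt=0)
    hops: int = Field(5, ge=1)
    angle_cutoff_deg: float = Field(45.0, gt=0)
    linearity_threshold: float = Field(0.95, gt=0, le=1)
    accept_factor: float = Field(1.6, gt=0)
    reconstruction: Literal["spherocylinder", "convex_hull", "partition"] = "spherocylinder"

    def to_segmentation_config(self, labeling: str = "interior") -> SegmentationConfig:
        tau = self.tau if self.tau is not None else {"interior": 0.94, "membrane": 0.88, "both": 0.88}[labeling]
        volume = expected_cell_volume(self.expected_diameter_um, self.expected_length_um)
        return SegmentationConfig(
            tau=tau,
            min_volume_fraction=self.min_volume_fraction,
            dilation_radius=self.dilation_radius,
            cv_params=CVFilterParams(
                rho=self.rho,
                min_size_fraction=self.min_size_fraction,
                expected_cell_volume=volume,
            ),
            lcuts=LCutsParams(
                sigma_d=self.sigma_d_um,
                sigma_t=self.sigma_t,
                r=self.r_um2,
                cell_length=self.expected_length_um,
                cell_diameter=self.expected_diameter_um,
                hops=self.hops,
                angle_cutoff_deg=self.angle_cutoff_deg,
                linearity_threshold=self.linearity_threshold,
                accept_factor=self.accept_factor,
            ),
            reconstruction=self.reconstruction,
        )


class EvaluationConfig(BaseModel):
    iou_threshold: float = Field(0.5, gt=0, lt=1)
    curve_thresholds: list[float] = Field(
        default_factory=lambda: [round(t, 2) for t in np.arange(0.05, 1.0, 0.05)]
    )
    density_tile_shape: tuple[int, int, int] = (8, 64, 64)
    density_top_k: int = Field(10, ge=1)


class PipelineConfig(BaseModel):
    """Master configuration for the simulate→render→segment→evaluate loop."""

    seed: int = 0
    voxel_size_um: tuple[float, float, float] = (0.1, 0.1, 0.1)
    grid_margin_um: float = Field(0.8, ge=0)
    arrangement: ArrangementConfig = Field(default_factory=ArrangementConfig)
    imaging: ImagingConfig = Field(default_factory=ImagingConfig)
    segmentation: SegmentationSettings = Field(default_factory=SegmentationSettings)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)
    confidence_path: Optional[str] = None  # externally produced confidence maps
    out_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False))
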