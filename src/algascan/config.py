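"""Validated pipeline configuration (YAML-loadable, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilterConfig(_Strict):
    length_mm: float = 47.8
    cwl_start: float = 400.0
    cwl_end: float = 700.0
    fwhm_start: float = Field(3.0, gt=0)
    fwhm_end: float = Field(9.0, gt=0)
    peak_transmittance: float = Field(1.0, ge=0, le=1)


class CameraConfig(_Strict):
    rows: int = Field(128, ge=2)
    cols: int = Field(160, ge=1)
    frame_rate: float = Field(240.0, gt=0)
    bit_depth: int = Field(8, ge=1, le=16)
    gamma_exponent: float = Field(0.45, gt=0)


class ScanConfig(_Strict):
    n_frames: int = Field(240, ge=2)
    shift_slope: float = 0.2
    noise_sd: float = Field(0.005, ge=0)
    exposure_blur: bool = False


class SceneConfig(_Strict):
    layout: str = "four_species"
    margin: int = Field(16, ge=4)
    flat_reflectance: float = Field(0.5, ge=0, le=1)


class TrimConfig(_Strict):
    red: tuple[float, float] = (510.0, 660.0)
    green: tuple[float, float] = (465.0, 620.0)
    blue: tuple[float, float] = (430.0, 566.0)


class CubeConfig(_Strict):
    onset_threshold: float = Field(0.1, gt=0, lt=1)
    grid_points: int = Field(225, ge=9)
    band_min: float = 435.0
    band_max: float = 659.0
    trim: TrimConfig = TrimConfig()
    n_shift_columns: int = Field(8, ge=1)


class CalibConfig(_Strict):
    grey_reflectance: float = Field(0.1, gt=0, le=1)
    savgol_order: int = Field(2, ge=1)
    savgol_window: int = Field(9, ge=3)
    bin_factor: int = Field(5, ge=1)


class ModelConfig(_Strict):
    n_bands: int = Field(45, ge=4)
    n_classes: int = Field(5, ge=2)
    conv1_filters: int = Field(32, ge=1)
    conv2_filters: int = Field(64, ge=1)
    kernel_size: int = Field(3, ge=1)
    pool_size: int = Field(2, ge=1)
    dropout: float = Field(0.25, ge=0, lt=1)
    dense_units: int = Field(128, ge=1)


class TrainingConfig(_Strict):
    epochs: int = Field(300, ge=1)
    batch_size: int = Field(256, ge=1)
    learning_rate: float = Field(1e-3, gt=0)
    train_fraction: float = Field(0.9, gt=0, lt=1)


class PipelineConfig(_Strict):
    """All tunables of the simulate/reconstruct/classify pipeline."""

    filter: FilterConfig = FilterConfig()
    camera: CameraConfig = CameraConfig()
    scan: ScanConfig = ScanConfig()
    scene: SceneConfig = SceneConfig()
    cube: CubeConfig = CubeConfig()
    calibration: CalibConfig = CalibConfig()
    model: ModelConfig = ModelConfig()
    training: TrainingConfig = TrainingConfig()

    @model_validator(mode="after")
    def _bands_consistent(self):
        if self.cube.grid_points % self.calibration.bin_factor != 0:
            raise ValueError(
                "cube.grid_points must be divisible by calibration.bin_factor"
            )
        if self.cube.grid_points // self.calibration.bin_factor != self.model.n_bands:
            raise ValueError(
                "grid_points / bin_factor must equal model.n_bands"
            )
        return self


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config, or the defaults when no path is given."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**data)
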