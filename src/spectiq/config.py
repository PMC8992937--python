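"""Schema-validated pipeline configuration (YAML-friendly, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .exceptions import ConfigurationError

SCHEMA_VERSION = 1


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Section):
    total_activity_mbq: float = Field(214.2, gt=0)
    stock_volume_ml: float = Field(1200.0, gt=0)
    background_compartment_volume_ml: float = Field(9787.0, gt=0)
    voxel_size_mm: float = Field(4.8, gt=0)
    grid: tuple[int, int, int] = (128, 128, 128)
    supersampling: int = Field(4, ge=1)
    lung_insert: bool = False


class AcquisitionSection(_Section):
    n_views_per_head: int = Field(60, ge=1)
    n_heads: int = Field(2, ge=1)
    arc_deg: float = Field(360.0, gt=0)
    pixel_size_mm: float = Field(4.8, gt=0)
    orbit_radius_mm: float = Field(250.0, gt=0)
    time_per_view_s: float = Field(15.0, gt=0)
    n_gate_bins: int = Field(15, ge=1)
    total_counts: float = Field(1.0e6, gt=0)
    collimator_fwhm_intercept_mm: float = Field(4.0, ge=0)
    collimator_fwhm_slope: float = Field(0.05, ge=0)
    seed: int = 0


class ReconSection(_Section):
    n_iterations: int = Field(12, ge=1)
    n_subsets: int = Field(8, ge=1)
    postfilter_fwhm_mm: float = Field(8.0, ge=0)
    attenuation: bool = True
    resolution_recovery: bool = True


class AnalysisSection(_Section):
    margin_mm: float = Field(15.0, gt=0)
    sd_roi_mode: str = "between"


class SweepSection(_Section):
    durations_s: tuple[float, ...] = (3.0, 8.0, 15.0)
    iteration_grid: tuple[int, ...] = (4, 8, 12, 16, 20, 24)
    fwhm_grid_mm: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0)
    seeds: tuple[int, ...] = (0,)
    convergence_threshold_percent: float = Field(3.5, gt=0)


class PipelineConfig(_Section):
    schema_version: int = SCHEMA_VERSION
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    acquisition: AcquisitionSection = Field(default_factory=AcquisitionSection)
    recon: ReconSection = Field(default_factory=ReconSection)
    analysis: AnalysisSection = Field(default_factory=AnalysisSection)
    sweep: SweepSection = Field(default_factory=SweepSection)

    @model_validator(mode="after")
    def _cross_checks(self) -> "PipelineConfig":
        total = self.acquisition.n_views_per_head * self.acquisition.n_heads
        if total % self.recon.n_subsets != 0:
            raise ConfigurationError(
                f"{self.recon.n_subsets} subsets do not divide {total} projections"
            )
        if self.phantom.grid[0] != self.phantom.grid[1]:
            raise ConfigurationError("transaxial grid must be square")
        bin_s = self.acquisition.time_per_view_s / self.acquisition.n_gate_bins
        for d in self.sweep.durations_s:
            k = d / bin_s
            if abs(k - round(k)) > 1e-9 or not 1 <= round(k) <= self.acquisition.n_gate_bins:
                raise ConfigurationError(f"duration {d} s not reachable from the gate bins")
        return self


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        for dotted, value in overrides.items():
            section, key = dotted.split(".", 1)
            data.setdefault(section, {})[key] = value
    try:
        return PipelineConfig(**data)
    except ConfigurationError:
        raise
    except Exception as exc:
        raise ConfigurationError(str(exc)) from exc
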