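"""Dual-head step-and-shoot SPECT acquisition simulation with gated bins.

A dual-head camera acquires 60 views per detector (120 projections) over a
360 degree circular orbit.  To emulate shorter scans from a single
acquisition, each view is split into ``n_gate_bins`` equal-duration gate
bins — independent Poisson realizations that can later be summed: bins 1-3,
1-8 and 1-15 of a 15 x 1 s gated acquisition reproduce 3, 8 and 15 s per
view.  Each (bin, view) pair draws from its own deterministic substream of
the master seed, so changing the bin count never perturbs other bins.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import InvalidParameterError
from .phantom import VoxelPhantom
from .projector import SystemModel


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Step-and-shoot orbit and detector description."""

    n_views_per_head: int = 60
    n_heads: int = 2
    arc_deg: float = 360.0
    matrix: tuple[int, int] = (128, 128)
    pixel_size_mm: float = 4.8
    orbit_radius_mm: float = 250.0
    time_per_view_s: float = 15.0
    collimator_fwhm_intercept_mm: float = 4.0
    collimator_fwhm_slope: float = 0.05
    sensitivity_cps: float = 1.0  # counts/s per (kBq/ml * voxel path)

    def __post_init__(self) -> None:
        if self.n_views_per_head < 1 or self.n_heads < 1:
            raise InvalidParameterError("need at least one head and one view")
        if self.pixel_size_mm <= 0 or self.time_per_view_s <= 0:
            raise InvalidParameterError("pixel size and time per view must be > 0")
        if self.sensitivity_cps <= 0:
            raise InvalidParameterError("sensitivity must be > 0")

    @property
    def total_projections(self) -> int:
        return self.n_views_per_head * self.n_heads

    @property
    def angles_deg(self) -> np.ndarray:
        """View azimuths: heads evenly offset, views evenly stepped."""
        step = self.arc_deg / self.total_projections
        return step * np.arange(self.total_projections)

    def total_scan_time_s(self, time_per_view_s: float | None = None) -> float:
        """Wall-clock scan time: heads acquire simultaneously."""
        t = self.time_per_view_s if time_per_view_s is None else time_per_view_s
        return self.n_views_per_head * t


@dataclass(frozen=True)
class ProjectionStack:
    """Gated per-view count data plus acquisition metadata.

    ``counts`` is indexed (gate_bin, view, row, col); integer-valued when
    Poisson noise has been applied.
    """

    counts: np.ndarray
    geometry: AcquisitionGeometry
    n_gate_bins: int
    bin_duration_s: float
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if self.counts.ndim != 4 or self.counts.shape[0] != self.n_gate_bins:
            raise InvalidParameterError("counts must be (gate_bin, view, row, col)")
        if self.counts.shape[1] != self.geometry.total_projections:
            raise InvalidParameterError("view axis must match the geometry")
        if np.any(self.counts < 0):
            raise InvalidParameterError("counts must be non-negative")
        if self.bin_duration_s <= 0:
            raise InvalidParameterError("bin duration must be > 0")

    @property
    def total_duration_s(self) -> float:
        return self.n_gate_bins * self.bin_duration_s


def make_system_model(
    phantom: VoxelPhantom,
    geometry: AcquisitionGeometry,
    attenuation: bool = True,
    blur: bool = True,
) -> SystemModel:
    """Build the projector for a phantom/geometry pair (grids must match)."""
    if abs(phantom.voxel_size_mm - geometry.pixel_size_mm) > 1e-9:
        raise InvalidParameterError(
            "voxel and detector pixel size differ; resample the phantom first"
        )
    return SystemModel(
        grid_shape=phantom.shape,
        voxel_size_mm=phantom.voxel_size_mm,
        angles_deg=geometry.angles_deg,
        orbit_radius_mm=geometry.orbit_radius_mm,
        mu_map=phantom.mu_map if attenuation else None,
        fwhm_intercept_mm=geometry.collimator_fwhm_intercept_mm,
        fwhm_slope=geometry.collimator_fwhm_slope,
        attenuation=attenuation,
        blur=blur,
    )


def forward_project(
    phantom: VoxelPhantom,
    geometry: AcquisitionGeometry,
    attenuation: bool = True,
    blur: bool = True,
    model: SystemModel | None = None,
) -> np.ndarray:
    """Noise-free expected count rates (counts/s), shape (view, row, col)."""
    if model is None:
        model = make_system_model(phantom, geometry, attenuation, blur)
    return geometry.sensitivity_cps * model.forward(phantom.activity)


def calibrate_sensitivity(
    noise_free_unit_cps: np.ndarray, time_per_view_s: float, total_counts: float
) -> float:
    """Sensitivity making the full acquisition total ``total_counts``.

    ``noise_free_unit_cps`` are unit-sensitivity rates (sensitivity 1.0).
    """
    base = float(noise_free_unit_cps.sum()) * time_per_view_s
    if base <= 0:
        raise InvalidParameterError("cannot calibrate on an all-zero projection")
    return total_counts / base


def _bin_rng(seed: int, bin_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(bin_index,)))


def simulate_gated_acquisition(
    noise_free_cps: np.ndarray,
    geometry: AcquisitionGeometry,
    n_gate_bins: int = 15,
    seed: int = 0,
    time_per_view_s: float | None = None,
) -> ProjectionStack:
    """Draw independent Poisson gate bins around the noise-free rates.

    Each bin has expectation ``noise_free_cps * time_per_view / n_gate_bins``
    — a 15-bin split of a 15 s view yields fifteen 1 s acquisitions.
    """
    if n_gate_bins < 1:
        raise InvalidParameterError("need at least one gate bin")
    t = geometry.time_per_view_s if time_per_view_s is None else time_per_view_s
    if t <= 0:
        raise InvalidParameterError("time per view must be > 0")
    lam = np.asarray(noise_free_cps, dtype=np.float64) * (t / n_gate_bins)
    counts = np.empty((n_gate_bins,) + lam.shape, dtype=np.int64)
    for b in range(n_gate_bins):
        counts[b] = _bin_rng(seed, b).poisson(lam)
    return ProjectionStack(
        counts=counts,
        geometry=geometry,
        n_gate_bins=n_gate_bins,
        bin_duration_s=t / n_gate_bins,
        noise_seed=seed,
    )


def sum_bins(stack: ProjectionStack, bin_range: tuple[int, int]) -> ProjectionStack:
    """Sum an inclusive 1-based bin range into a single-bin stack.

    Summing bins 1-3, 1-8 or 1-15 of a 15-bin, 15 s/view acquisition yields
    the 3, 8 and 15 s/view datasets.
    """
    lo, hi = bin_range
    if not (1 <= lo <= hi <= stack.n_gate_bins):
        raise IndexError(f"bin range {bin_range} outside [1, {stack.n_gate_bins}]")
    summed = stack.counts[lo - 1 : hi].sum(axis=0, keepdims=True)
    return replace(
        stack,
        counts=summed,
        n_gate_bins=1,
        bin_duration_s=(hi - lo + 1) * stack.bin_duration_s,
    )
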