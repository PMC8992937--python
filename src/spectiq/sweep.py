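"""Acquisition-time / reconstruction-parameter sweep orchestration.

One gated acquisition per seed supplies nested 3/8/15 s datasets (the
shorter durations are partial bin sums of the same scan, exactly the gated
study design).  For each duration the OSEM run is warm-started: a single
pass to the largest requested iteration count is snapshotted at every grid
point, which is valid because OSEM iterations compose.  Each snapshot is
post-filtered at every requested FWHM and scored with the NEMA metric
suite, yielding a tidy table of RC/BV/CNR per (duration, iterations, fwhm,
sphere, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import (
    AcquisitionGeometry,
    ProjectionStack,
    make_system_model,
    simulate_gated_acquisition,
    sum_bins,
)
from .exceptions import InvalidParameterError, UndefinedMetricError
from .nema import RoiEvaluator, RoiLayout
from .phantom import VoxelPhantom
from .recon import ReconParams, Volume, cylindrical_support, gaussian_postfilter_3d, osem_iterations

TIDY_COLUMNS = [
    "seed", "duration_s", "n_iterations", "n_subsets", "postfilter_fwhm_mm",
    "sphere_diameter_mm", "rc_percent", "bv_percent", "cnr", "rose_visible",
]


@dataclass(frozen=True)
class SweepConfig:
    """Grid of study conditions."""

    durations_s: tuple[float, ...] = (3.0, 8.0, 15.0)
    iteration_grid: tuple[int, ...] = (4, 8, 12, 16, 20, 24)
    n_subsets: int = 8
    fwhm_grid_mm: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0)
    seeds: tuple[int, ...] = (0,)
    convergence_threshold_percent: float = 3.5

    def __post_init__(self) -> None:
        if not (self.durations_s and self.iteration_grid and self.fwhm_grid_mm and self.seeds):
            raise InvalidParameterError("all sweep grids must be non-empty")
        if list(self.iteration_grid) != sorted(set(self.iteration_grid)):
            raise InvalidParameterError("iteration grid must be strictly increasing")
        if self.convergence_threshold_percent <= 0:
            raise InvalidParameterError("convergence threshold must be > 0")


@dataclass
class SweepTable:
    """Tidy per-cell results plus seed-aggregated summaries."""

    table: pd.DataFrame
    config: SweepConfig
    failed_cells: list[dict] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean and SD of each metric across seeds."""
        keys = ["duration_s", "n_iterations", "n_subsets", "postfilter_fwhm_mm",
                "sphere_diameter_mm"]
        return (
            self.table.groupby(keys)[["rc_percent", "bv_percent", "cnr"]]
            .agg(["mean", "std"])
            .reset_index()
        )

    def cnr_wide(self) -> pd.DataFrame:
        """CNR by iteration number x (duration, sphere), 8 mm-filter style table."""
        return self.table.pivot_table(
            index="n_iterations",
            columns=["duration_s", "sphere_diameter_mm"],
            values="cnr",
            aggfunc="mean",
        )


def run_parameter_sweep(
    phantom: VoxelPhantom,
    noise_free_cps: np.ndarray,
    geometry: AcquisitionGeometry,
    config: SweepConfig,
    layout: RoiLayout,
    ratio: float,
    n_gate_bins: int = 15,
    sd_roi_mode: str = "between",
) -> SweepTable:
    """Run the full study grid; deterministic given ``config.seeds``.

    ``noise_free_cps`` are the expected count rates of the full acquisition
    (including sensitivity); each seed draws its own gated Poisson stack
    from them.  A failed reconstruction marks its cells and the sweep
    continues.
    """
    bin_s = geometry.time_per_view_s / n_gate_bins
    for d in config.durations_s:
        n_bins = d / bin_s
        if abs(n_bins - round(n_bins)) > 1e-9 or not (1 <= round(n_bins) <= n_gate_bins):
            raise InvalidParameterError(
                f"duration {d} s is not a whole number of {bin_s} s gate bins"
            )
    model = make_system_model(phantom, geometry, attenuation=True, blur=True)
    evaluator = RoiEvaluator(layout, ratio, phantom.voxel_size_mm, phantom.origin_mm,
                             phantom.shape[:2], sd_roi_mode=sd_roi_mode)
    init = np.where(cylindrical_support(phantom.shape), 1.0, 0.0)
    rows: list[dict] = []
    failed: list[dict] = []
    max_it = max(config.iteration_grid)
    for seed in config.seeds:
        stack = simulate_gated_acquisition(noise_free_cps, geometry, n_gate_bins, seed=seed)
        for duration in config.durations_s:
            sub = sum_bins(stack, (1, int(round(duration / bin_s))))
            scale = geometry.sensitivity_cps * sub.bin_duration_s
            data = sub.counts[0] / scale
            try:
                it_stream = osem_iterations(data, model, max_it, config.n_subsets, init)
                for it_count, x in enumerate(it_stream, start=1):
                    if it_count not in config.iteration_grid:
                        continue
                    vol = Volume(values=x.copy(), voxel_size_mm=phantom.voxel_size_mm)
                    for fwhm in config.fwhm_grid_mm:
                        filtered = gaussian_postfilter_3d(vol, fwhm)
                        for res in evaluator(filtered.values):
                            rows.append({
                                "seed": seed,
                                "duration_s": duration,
                                "n_iterations": it_count,
                                "n_subsets": config.n_subsets,
                                "postfilter_fwhm_mm": fwhm,
                                "sphere_diameter_mm": res.sphere_diameter_mm,
                                "rc_percent": res.rc_percent,
                                "bv_percent": res.bv_percent,
                                "cnr": res.cnr,
                                "rose_visible": res.rose_visible,
                            })
            except Exception as exc:  # pragma: no cover - defensive
                failed.append({"seed": seed, "duration_s": duration, "error": str(exc)})
    return SweepTable(table=pd.DataFrame(rows, columns=TIDY_COLUMNS), config=config,
                      failed_cells=failed)


def detect_convergence(
    iterations: np.ndarray, values: np.ndarray, threshold_percent: float = 3.5
) -> int | None:
    """Smallest grid iteration after which successive RC changes stay small.

    Returns the first grid iteration i_k such that every subsequent
    successive relative change |v(i+1) - v(i)| / v(i) stays below
    ``threshold_percent`` / 100, or None if no such point exists (the last
    grid point alone never qualifies).
    """
    it = np.asarray(iterations, dtype=float)
    v = np.asarray(values, dtype=float)
    if it.ndim != 1 or it.shape != v.shape or it.size < 2:
        raise InvalidParameterError("need matched 1D series with >= 2 points")
    if np.any(np.diff(it) <= 0):
        raise InvalidParameterError("iteration grid must be increasing")
    if np.any(v[:-1] == 0):
        raise UndefinedMetricError("relative change undefined where the value is 0")
    rel = np.abs(np.diff(v)) / np.abs(v[:-1])
    ok = rel < threshold_percent / 100.0
    for k in range(len(it) - 1):
        if ok[k:].all():
            return int(it[k])
    return None
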