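"""NEMA NU 2-2018 style ROI layout and image-quality metrics.

Per hot sphere s the analysis computes

    RC_s  = 100 * (C_H,s / C_B,s - 1) / (R - 1)          contrast recovery, %
    BV_s  = 100 * SD_s / C_B,s                            background variability, %
    SD_s  = sqrt( sum_k (C_B,s,k - C_B,s)^2 / (K - 1) )   over K background ROIs
    CNR_s = (C_H,s - C_B,s) / SD_ROI                      contrast-to-noise ratio

where C_H,s is the mean pixel value in the sphere ROI (diameter equal to
the sphere's internal diameter, on the slice through the sphere centres),
C_B,s the mean of the K = 60 background ROI means of matching diameter
(12 positions x 5 analysis slices), and R the true sphere-to-background
concentration ratio.  A sphere is deemed visible when CNR > 5 (Rose
criterion, strict inequality).

SD_ROI is configurable: by default it equals SD_s (the only SD the metric
suite defines); alternatively the mean within-ROI pixel SD over the
background ROIs can be used.  The choice is recorded in each result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError, LayoutError, UndefinedMetricError
from .phantom import PhantomSpec, VoxelPhantom

BACKGROUND_ROI_DIAMETER_MM = 37.0
DEFAULT_MARGIN_MM = 15.0
ROSE_THRESHOLD = 5.0


@dataclass(frozen=True)
class RoiLayout:
    """Sphere and background ROI geometry on a voxel grid."""

    central_slice: int
    analysis_slices: tuple[int, ...]  # 5 slices: central and +-1, +-2
    sphere_centers_mm: np.ndarray  # (6, 2) transaxial centres
    roi_diameters_mm: tuple[float, ...]  # per-sphere ROI = internal diameter
    background_centers_mm: np.ndarray  # (12, 2)
    margin_mm: float = DEFAULT_MARGIN_MM

    def __post_init__(self) -> None:
        if len(self.analysis_slices) != 5:
            raise InvalidParameterError("expected 5 analysis slices")
        if self.background_centers_mm.shape[0] != 12:
            raise InvalidParameterError("expected 12 background positions")

    @property
    def n_background_rois(self) -> int:
        """Background ROIs per diameter: 12 positions x 5 slices."""
        return self.background_centers_mm.shape[0] * len(self.analysis_slices)


@dataclass(frozen=True)
class RoiStats:
    """Per-sphere ROI statistics feeding the metrics."""

    c_hot: float  # C_H,s: mean pixel value in the sphere ROI
    c_bkg: float  # C_B,s: mean of the K background ROI means
    sd: float  # SD_s: sample SD (K-1) of the background ROI means
    sd_roi: float  # noise term of the CNR
    k: int  # number of background ROIs (60)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise InvalidParameterError("need at least two background ROIs")
        if self.sd < 0:
            raise InvalidParameterError("SD must be >= 0")


@dataclass(frozen=True)
class IQResult:
    """Image-quality metrics for one sphere under one condition."""

    sphere_diameter_mm: float
    rc_percent: float
    bv_percent: float
    cnr: float
    rose_visible: bool
    stats: RoiStats
    condition: dict = field(default_factory=dict)


# -- metric formulas ---------------------------------------------------------


def contrast_recovery(stats: RoiStats, ratio: float) -> float:
    """Percent contrast recovery; 100 means the full R:1 contrast survived."""
    if ratio <= 1:
        raise InvalidParameterError("concentration ratio must exceed 1")
    if stats.c_bkg == 0:
        raise UndefinedMetricError("contrast recovery undefined for zero background")
    return 100.0 * (stats.c_hot / stats.c_bkg - 1.0) / (ratio - 1.0)


def background_variability(stats: RoiStats) -> float:
    """Percent coefficient of variation of the background ROI means."""
    if stats.c_bkg == 0:
        raise UndefinedMetricError("background variability undefined for zero background")
    return 100.0 * stats.sd / stats.c_bkg


def cnr(stats: RoiStats) -> float:
    """Contrast-to-noise ratio (C_H - C_B) / SD_ROI."""
    if stats.sd_roi == 0:
        raise UndefinedMetricError("CNR undefined for zero background SD")
    return (stats.c_hot - stats.c_bkg) / stats.sd_roi


def rose_visible(cnr_value: float) -> bool:
    """Rose criterion: visible iff CNR strictly exceeds 5."""
    return cnr_value > ROSE_THRESHOLD


# -- ROI geometry ------------------------------------------------------------


def circle_mask(
    grid_shape_2d: tuple[int, int],
    voxel_size_mm: float,
    origin_2d: tuple[float, float],
    center_mm: tuple[float, float],
    diameter_mm: float,
) -> np.ndarray:
    """Pixels whose centre lies within the circle (membership rule)."""
    xs = origin_2d[0] + voxel_size_mm * np.arange(grid_shape_2d[0])
    ys = origin_2d[1] + voxel_size_mm * np.arange(grid_shape_2d[1])
    r = diameter_mm / 2.0
    return (xs[:, None] - center_mm[0]) ** 2 + (ys[None, :] - center_mm[1]) ** 2 <= r * r


def circle_weights(
    grid_shape_2d: tuple[int, int],
    voxel_size_mm: float,
    origin_2d: tuple[float, float],
    center_mm: tuple[float, float],
    diameter_mm: float,
    weighting: str = "center",
    supersampling: int = 16,
) -> np.ndarray:
    """Per-pixel ROI weights.

    ``center``: binary weights from the pixel-centre membership rule.
    ``area``: fractional pixel-area-inside-circle weights (supersampled);
    removes the sizeable boundary-pixel bias of the centre rule when the
    ROI spans only a few pixels.
    """
    if weighting == "center":
        return circle_mask(grid_shape_2d, voxel_size_mm, origin_2d, center_mm,
                           diameter_mm).astype(np.float64)
    if weighting != "area":
        raise InvalidParameterError("weighting must be 'center' or 'area'")
    s = supersampling
    off = ((np.arange(s) + 0.5) / s - 0.5) * voxel_size_mm
    xs = (origin_2d[0] + voxel_size_mm * np.arange(grid_shape_2d[0]))[:, None] + off
    ys = (origin_2d[1] + voxel_size_mm * np.arange(grid_shape_2d[1]))[:, None] + off
    r = diameter_mm / 2.0
    inside = (
        (xs.ravel()[:, None] - center_mm[0]) ** 2
        + (ys.ravel()[None, :] - center_mm[1]) ** 2
    ) <= r * r
    return inside.reshape(grid_shape_2d[0], s, grid_shape_2d[1], s).mean(axis=(1, 3))


def build_roi_layout(
    spec: PhantomSpec,
    grid_shape: tuple[int, int, int],
    voxel_size_mm: float,
    origin_mm: tuple[float, float, float],
    margin_mm: float = DEFAULT_MARGIN_MM,
    slice_offsets: tuple[int, ...] = (-2, -1, 0, 1, 2),
) -> RoiLayout:
    """Place sphere ROIs and search 12 valid background positions.

    The central slice passes through the sphere centres; four more analysis
    slices sit at the given slice offsets.  Background 37 mm ROIs must stay
    ``margin_mm`` clear of the phantom margin and of every hot sphere
    (edge-to-edge); positions come from a deterministic, seed-free greedy
    scan of a polar candidate grid (outer radii first), keeping candidates
    at least 37 mm apart so the ROIs do not overlap each other.
    """
    nz = grid_shape[2]
    zc = (np.asarray(spec.sphere_centers_mm)[:, 2].mean() - origin_mm[2]) / voxel_size_mm
    central = int(round(zc))
    slices = tuple(central + o for o in slice_offsets)
    if min(slices) < 0 or max(slices) >= nz:
        raise LayoutError("analysis slices fall outside the grid")

    r_roi = BACKGROUND_ROI_DIAMETER_MM / 2.0
    centers = np.asarray(spec.sphere_centers_mm)[:, :2]
    radii = np.asarray(spec.sphere_diameters_mm) / 2.0

    def valid(p: np.ndarray) -> bool:
        if spec.body.margin_distance(p[0], p[1]) < margin_mm + r_roi:
            return False
        d = np.linalg.norm(centers - p, axis=1)
        return bool(np.all(d >= margin_mm + r_roi + radii))

    # polar candidate grid, outer rings first, fine angular steps
    max_r = spec.body.width_mm / 2.0
    chosen: list[np.ndarray] = []
    for radius in np.arange(max_r, -1.0, -voxel_size_mm / 2.0):
        if radius == 0:
            cands = [np.zeros(2)]
        else:
            n_ang = max(int(round(2 * math.pi * radius / 5.0)), 8)
            ang = 2 * math.pi * np.arange(n_ang) / n_ang
            cands = list(np.column_stack([radius * np.cos(ang), radius * np.sin(ang)]))
        for p in cands:
            if len(chosen) == 12:
                break
            if not valid(p):
                continue
            if chosen and min(np.linalg.norm(q - p) for q in chosen) < 2 * r_roi:
                continue
            chosen.append(p)
        if len(chosen) == 12:
            break
    if len(chosen) < 12:
        raise LayoutError(
            f"only {len(chosen)} valid background positions found; "
            f"margin rule {margin_mm} mm may be infeasible for this outline"
        )
    return RoiLayout(
        central_slice=central,
        analysis_slices=slices,
        sphere_centers_mm=centers,
        roi_diameters_mm=tuple(spec.sphere_diameters_mm),
        background_centers_mm=np.asarray(chosen),
        margin_mm=margin_mm,
    )


# -- evaluation --------------------------------------------------------------


def _weighted_mean_sd(plane: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    w = weights.sum()
    if w <= 0:
        raise LayoutError("ROI contains no pixels at this grid resolution")
    mean = float((plane * weights).sum() / w)
    n_eff = int((weights > 0).sum())
    if n_eff < 2:
        return mean, 0.0
    var = float((weights * (plane - mean) ** 2).sum() / w) * n_eff / (n_eff - 1)
    return mean, math.sqrt(max(var, 0.0))


class RoiEvaluator:
    """Caches ROI weight maps for repeated evaluation of one layout/grid.

    ``sd_roi_mode``: "between" uses SD_s (SD over the 60 background ROI
    means) as the CNR noise term; "within" uses the mean within-ROI pixel
    SD over those ROIs.  ``roi_weighting``: "center" (pixel-centre
    membership) or "area" (fractional-area weights).
    """

    def __init__(
        self,
        layout: RoiLayout,
        ratio: float,
        voxel_size_mm: float,
        origin_mm: tuple[float, float, float],
        grid_shape_2d: tuple[int, int],
        sd_roi_mode: str = "between",
        roi_weighting: str = "center",
    ):
        if sd_roi_mode not in ("between", "within"):
            raise InvalidParameterError("sd_roi_mode must be 'between' or 'within'")
        self.layout = layout
        self.ratio = ratio
        self.sd_roi_mode = sd_roi_mode
        self.roi_weighting = roi_weighting
        origin2d = origin_mm[:2]
        self._sphere_w = [
            circle_weights(grid_shape_2d, voxel_size_mm, origin2d,
                           tuple(layout.sphere_centers_mm[s]), d, roi_weighting)
            for s, d in enumerate(layout.roi_diameters_mm)
        ]
        self._bkg_w = [
            [circle_weights(grid_shape_2d, voxel_size_mm, origin2d, tuple(bc), d,
                            roi_weighting)
             for bc in layout.background_centers_mm]
            for d in layout.roi_diameters_mm
        ]

    def __call__(self, volume: np.ndarray, condition: dict | None = None) -> list[IQResult]:
        vol = np.asarray(volume)
        layout = self.layout
        cond = dict(condition or {})
        cond["sd_roi_mode"] = self.sd_roi_mode
        cond["roi_weighting"] = self.roi_weighting
        results = []
        for s, diameter in enumerate(layout.roi_diameters_mm):
            c_hot, _ = _weighted_mean_sd(vol[:, :, layout.central_slice], self._sphere_w[s])
            means, within_sds = [], []
            for w in self._bkg_w[s]:
                for z in layout.analysis_slices:
                    m, sd_w = _weighted_mean_sd(vol[:, :, z], w)
                    means.append(m)
                    within_sds.append(sd_w)
            means_arr = np.asarray(means)
            c_bkg = float(means_arr.mean())
            sd = float(means_arr.std(ddof=1))
            sd_roi = sd if self.sd_roi_mode == "between" else float(np.mean(within_sds))
            stats = RoiStats(c_hot=c_hot, c_bkg=c_bkg, sd=sd, sd_roi=sd_roi, k=len(means))
            if sd_roi == 0.0:
                # noiseless degenerate image: RC/BV are still well defined,
                # CNR is 0/0 (uniform) or infinite (noise-free contrast)
                cnr_value = float("nan") if c_hot == c_bkg else math.inf * np.sign(c_hot - c_bkg)
            else:
                cnr_value = cnr(stats)
            results.append(
                IQResult(
                    sphere_diameter_mm=diameter,
                    rc_percent=contrast_recovery(stats, self.ratio),
                    bv_percent=background_variability(stats),
                    cnr=cnr_value,
                    rose_visible=rose_visible(cnr_value),
                    stats=stats,
                    condition=cond,
                )
            )
        return results


def evaluate_volume(
    volume: np.ndarray,
    layout: RoiLayout,
    ratio: float,
    voxel_size_mm: float,
    origin_mm: tuple[float, float, float],
    sd_roi_mode: str = "between",
    roi_weighting: str = "center",
    condition: dict | None = None,
) -> list[IQResult]:
    """Compute RC/BV/CNR for every sphere on a reconstructed volume."""
    ev = RoiEvaluator(layout, ratio, voxel_size_mm, origin_mm,
                      np.asarray(volume).shape[:2], sd_roi_mode, roi_weighting)
    return ev(volume, condition)


def evaluate_phantom_volume(
    phantom_like, layout: RoiLayout, ratio: float, **kwargs
) -> list[IQResult]:
    """Convenience wrapper accepting VoxelPhantom or recon Volume objects."""
    if isinstance(phantom_like, VoxelPhantom):
        return evaluate_volume(
            phantom_like.activity, layout, ratio, phantom_like.voxel_size_mm,
            phantom_like.origin_mm, **kwargs
        )
    values = phantom_like.values
    vx = phantom_like.voxel_size_mm
    origin = tuple(-(n - 1) / 2.0 * vx for n in values.shape)
    return evaluate_volume(values, layout, ratio, vx, origin, **kwargs)
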