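"""Digital NEMA IEC body phantom.

The NEMA IEC body phantom is a torso-shaped fillable cavity holding six
fillable spheres of graded internal diameter (37, 28, 22, 17, 13, 10 mm).
This module reproduces the radiochemical fill arithmetic (a single stock
solution is split between the spheres and a diluted background compartment,
fixing the sphere-to-background activity concentration ratio) and rasterises
the phantom onto an isotropic voxel grid: an activity concentration map in
kBq/ml and a linear attenuation map in 1/cm.

Geometry conventions
--------------------
The phantom frame has its origin at the centre of the sphere ring; x/y span
the transaxial plane and z the scanner axis.  The torso cross-section is
approximated by a 300 x 230 mm stadium (a rectangle capped by two half
discs) extruded over the axial length.  Sphere centres default to the
standard arrangement on a 114.4 mm diameter circle at 60 degree spacing in a
single transaxial plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import GeometryError, InfeasiblePlanError, InvalidParameterError

#: Internal diameters (mm) of the six fillable spheres, descending.
SPHERE_DIAMETERS_MM: tuple[float, ...] = (37.0, 28.0, 22.0, 17.0, 13.0, 10.0)

#: Narrow-beam linear attenuation coefficient of water at 140 keV (1/cm).
MU_WATER_140KEV = 0.154


def sphere_volume_ml(diameter_mm: float) -> float:
    """Volume of a sphere of the given internal diameter, in ml."""
    return math.pi / 6.0 * diameter_mm**3 / 1000.0


@dataclass(frozen=True)
class FillPlan:
    """Radiochemical bookkeeping for one phantom preparation.

    A stock solution of ``total_activity_mbq`` in ``stock_volume_ml`` of
    water sets the sphere concentration; the spheres withdraw
    ``sphere_withdrawal_volume_ml`` of it and the remainder is diluted into
    the background compartment (final volume
    ``background_compartment_volume_ml``).
    """

    total_activity_mbq: float
    stock_volume_ml: float
    sphere_withdrawal_volume_ml: float
    background_compartment_volume_ml: float
    sphere_concentration_kbq_ml: float
    background_concentration_kbq_ml: float
    ratio: float  #: sphere-to-background concentration ratio R

    def __post_init__(self) -> None:
        for name in (
            "total_activity_mbq",
            "stock_volume_ml",
            "sphere_withdrawal_volume_ml",
            "background_compartment_volume_ml",
            "sphere_concentration_kbq_ml",
            "background_concentration_kbq_ml",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.sphere_withdrawal_volume_ml >= self.stock_volume_ml:
            raise InfeasiblePlanError(
                "sphere withdrawal volume must be smaller than the stock volume"
            )
        expected = self.sphere_concentration_kbq_ml / self.background_concentration_kbq_ml
        if not math.isclose(self.ratio, expected, rel_tol=1e-9):
            raise InvalidParameterError("ratio inconsistent with the two concentrations")


def compute_fill_plan(
    total_activity_mbq: float,
    stock_volume_ml: float,
    sphere_diameters_mm: tuple[float, ...] = SPHERE_DIAMETERS_MM,
    background_compartment_volume_ml: float = 9787.0,
) -> FillPlan:
    """Derive sphere/background concentrations from the preparation recipe.

    The stock concentration (``total_activity / stock_volume``) fills the
    spheres directly; the activity left after withdrawing the summed sphere
    volumes is diluted into the background compartment.  The concentration
    ratio R therefore depends only on the volumes, not on the activity.
    """
    if total_activity_mbq <= 0 or stock_volume_ml <= 0 or background_compartment_volume_ml <= 0:
        raise InvalidParameterError("activities and volumes must be > 0")
    if any(d <= 0 for d in sphere_diameters_mm):
        raise InvalidParameterError("sphere diameters must be > 0")
    withdrawal_ml = sum(sphere_volume_ml(d) for d in sphere_diameters_mm)
    if withdrawal_ml >= stock_volume_ml:
        raise InfeasiblePlanError(
            f"sphere withdrawal {withdrawal_ml:.1f} ml >= stock {stock_volume_ml:.1f} ml"
        )
    sphere_conc = total_activity_mbq * 1000.0 / stock_volume_ml  # kBq/ml
    remaining_kbq = (stock_volume_ml - withdrawal_ml) * sphere_conc
    background_conc = remaining_kbq / background_compartment_volume_ml
    return FillPlan(
        total_activity_mbq=total_activity_mbq,
        stock_volume_ml=stock_volume_ml,
        sphere_withdrawal_volume_ml=withdrawal_ml,
        background_compartment_volume_ml=background_compartment_volume_ml,
        sphere_concentration_kbq_ml=sphere_conc,
        background_concentration_kbq_ml=background_conc,
        ratio=sphere_conc / background_conc,
    )


@dataclass(frozen=True)
class BodyOutline:
    """Stadium-shaped torso cross-section extruded along z.

    The cross-section is the set of points within ``height/2`` of the
    horizontal segment ``|x| <= (width - height)/2`` — a rectangle with two
    semicircular caps, 300 x 230 mm by default.
    """

    width_mm: float = 300.0
    height_mm: float = 230.0
    axial_length_mm: float = 180.0

    def __post_init__(self) -> None:
        if self.height_mm <= 0 or self.width_mm < self.height_mm or self.axial_length_mm <= 0:
            raise InvalidParameterError("need width >= height > 0 and axial length > 0")

    @property
    def cap_radius_mm(self) -> float:
        return self.height_mm / 2.0

    @property
    def half_straight_mm(self) -> float:
        return (self.width_mm - self.height_mm) / 2.0

    def margin_distance(self, x, y):
        """Distance (mm) from interior points to the outline; negative outside."""
        dx = np.maximum(np.abs(np.asarray(x, dtype=float)) - self.half_straight_mm, 0.0)
        return self.cap_radius_mm - np.hypot(dx, y)

    def contains(self, x, y):
        return self.margin_distance(x, y) >= 0.0

    @property
    def cross_section_area_mm2(self) -> float:
        r, a = self.cap_radius_mm, self.half_straight_mm
        return math.pi * r * r + 4.0 * a * r

    @property
    def volume_ml(self) -> float:
        return self.cross_section_area_mm2 * self.axial_length_mm / 1000.0


def default_sphere_centers(
    ring_diameter_mm: float = 114.4, n: int = 6, start_angle_deg: float = 0.0
) -> np.ndarray:
    """Sphere centres on a transaxial ring at even angular spacing (z = 0)."""
    angles = np.deg2rad(start_angle_deg + 360.0 / n * np.arange(n))
    r = ring_diameter_mm / 2.0
    return np.column_stack([r * np.cos(angles), r * np.sin(angles), np.zeros(n)])


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and radiochemical description of the phantom."""

    fill_plan: FillPlan
    sphere_diameters_mm: tuple[float, ...] = SPHERE_DIAMETERS_MM
    sphere_centers_mm: np.ndarray = field(default_factory=default_sphere_centers)
    body: BodyOutline = field(default_factory=BodyOutline)
    mu_water_per_cm: float = MU_WATER_140KEV
    lung_insert: bool = False
    lung_radius_mm: float = 25.0
    lung_mu_per_cm: float = 0.04

    def __post_init__(self) -> None:
        centers = np.asarray(self.sphere_centers_mm, dtype=float)
        object.__setattr__(self, "sphere_centers_mm", centers)
        n = len(self.sphere_diameters_mm)
        if centers.shape != (n, 3):
            raise InvalidParameterError("need one 3D centre per sphere")
        if any(d <= 0 for d in self.sphere_diameters_mm):
            raise InvalidParameterError("sphere diameters must be > 0")
        if self.mu_water_per_cm < 0:
            raise InvalidParameterError("mu_water must be >= 0")
        radii = np.asarray(self.sphere_diameters_mm) / 2.0
        for i in range(n):
            for j in range(i + 1, n):
                gap = np.linalg.norm(centers[i] - centers[j]) - radii[i] - radii[j]
                if gap < 0:
                    raise GeometryError(f"spheres {i} and {j} overlap by {-gap:.1f} mm")
        margins = self.body.margin_distance(centers[:, 0], centers[:, 1])
        if np.any(margins < radii) or np.any(
            np.abs(centers[:, 2]) + radii > self.body.axial_length_mm / 2.0
        ):
            raise GeometryError("a sphere extends outside the body outline")

    @property
    def ratio(self) -> float:
        return self.fill_plan.ratio

    def total_activity_kbq(self) -> float:
        """Analytic activity content of the geometric phantom (kBq)."""
        sph = sum(sphere_volume_ml(d) for d in self.sphere_diameters_mm)
        fp = self.fill_plan
        return fp.sphere_concentration_kbq_ml * sph + fp.background_concentration_kbq_ml * (
            self.body.volume_ml - sph
        )


def default_phantom_spec(
    total_activity_mbq: float = 214.2,
    stock_volume_ml: float = 1200.0,
    background_compartment_volume_ml: float = 9787.0,
    **kwargs,
) -> PhantomSpec:
    """Phantom prepared per the standard recipe (178.5 / 21 kBq/ml, R = 8.5)."""
    plan = compute_fill_plan(
        total_activity_mbq, stock_volume_ml, SPHERE_DIAMETERS_MM, background_compartment_volume_ml
    )
    return PhantomSpec(fill_plan=plan, **kwargs)


@dataclass(frozen=True)
class VoxelPhantom:
    """Rasterised phantom: activity (kBq/ml) and attenuation (1/cm) grids."""

    activity: np.ndarray  # (nx, ny, nz)
    mu_map: np.ndarray  # same shape
    voxel_size_mm: float
    origin_mm: tuple[float, float, float]  # phantom-frame position of voxel (0,0,0) centre

    def __post_init__(self) -> None:
        if self.activity.shape != self.mu_map.shape:
            raise InvalidParameterError("activity and mu_map must share a shape")
        if np.any(self.activity < 0) or np.any(self.mu_map < 0):
            raise InvalidParameterError("activity and mu_map must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.activity.shape

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size_mm**3 / 1000.0

    def total_activity_kbq(self) -> float:
        return float(self.activity.sum()) * self.voxel_volume_ml

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin_mm[axis] + self.voxel_size_mm * np.arange(n)


def _centered_origin(grid_shape, voxel_size_mm):
    # phantom origin sits exactly on a voxel centre (index n//2 along each
    # axis) so the sphere plane coincides with an image slice
    return tuple(-(n // 2) * voxel_size_mm for n in grid_shape)


def _subsample_offsets(s: int) -> np.ndarray:
    return (np.arange(s) + 0.5) / s - 0.5


def voxelize_phantom(
    spec: PhantomSpec,
    voxel_size_mm: float = 4.8,
    grid_shape: tuple[int, int, int] = (128, 128, 128),
    supersampling: int = 4,
) -> VoxelPhantom:
    """Rasterise a :class:`PhantomSpec` onto an isotropic grid.

    Boundary voxels carry the sub-voxel volume-fraction-weighted
    concentration: each sphere and the body outline are sampled on a
    ``supersampling``-times finer lattice.  The body fraction factorises
    exactly into an in-plane fraction (supersampled) times an axial overlap
    fraction (exact), because the outline is an extrusion.  Deterministic:
    identical spec and grid give bit-identical arrays.
    """
    if voxel_size_mm <= 0:
        raise InvalidParameterError("voxel_size must be > 0")
    if supersampling < 1:
        raise InvalidParameterError("supersampling must be >= 1")
    nx, ny, nz = grid_shape
    origin = _centered_origin(grid_shape, voxel_size_mm)
    xs = origin[0] + voxel_size_mm * np.arange(nx)
    ys = origin[1] + voxel_size_mm * np.arange(ny)
    zs = origin[2] + voxel_size_mm * np.arange(nz)

    off = _subsample_offsets(supersampling) * voxel_size_mm
    # in-plane body fraction, supersampled
    fx = (xs[:, None] + off[None, :]).ravel()
    fy = (ys[:, None] + off[None, :]).ravel()
    inside = spec.body.contains(fx[:, None], fy[None, :]).astype(np.float64)
    frac2d = inside.reshape(nx, supersampling, ny, supersampling).mean(axis=(1, 3))
    # axial fraction, exact interval overlap
    half_l = spec.body.axial_length_mm / 2.0
    lo = np.maximum(zs - voxel_size_mm / 2.0, -half_l)
    hi = np.minimum(zs + voxel_size_mm / 2.0, half_l)
    frac_z = np.clip((hi - lo) / voxel_size_mm, 0.0, 1.0)
    body_frac = frac2d[:, :, None] * frac_z[None, None, :]

    sphere_frac = np.zeros(grid_shape, dtype=np.float64)
    for center, diam in zip(spec.sphere_centers_mm, spec.sphere_diameters_mm):
        r = diam / 2.0
        ilo, ihi = [], []
        for axis, c in enumerate(center):
            i0 = int(np.floor((c - r - origin[axis]) / voxel_size_mm - 0.5))
            i1 = int(np.ceil((c + r - origin[axis]) / voxel_size_mm + 0.5))
            if i0 < 0 or i1 > grid_shape[axis]:
                raise GeometryError(
                    f"sphere d={diam} mm extends outside the grid along axis {axis}"
                )
            ilo.append(i0)
            ihi.append(i1)
        sub = np.ix_(
            *[np.arange(ilo[a], ihi[a]) for a in range(3)]
        )
        coords = [
            (origin[a] + voxel_size_mm * np.arange(ilo[a], ihi[a]))[:, None] + off[None, :]
            for a in range(3)
        ]
        dx2 = ((coords[0] - center[0]) ** 2).ravel()
        dy2 = ((coords[1] - center[1]) ** 2).ravel()
        dz2 = ((coords[2] - center[2]) ** 2).ravel()
        in_sph = (
            dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :] <= r * r
        ).astype(np.float64)
        bx, by, bz = (ihi[a] - ilo[a] for a in range(3))
        s = supersampling
        frac = in_sph.reshape(bx, s, by, s, bz, s).mean(axis=(1, 3, 5))
        sphere_frac[sub] += frac

    sphere_frac = np.minimum(sphere_frac, body_frac)
    fp = spec.fill_plan
    activity = (
        fp.background_concentration_kbq_ml * (body_frac - sphere_frac)
        + fp.sphere_concentration_kbq_ml * sphere_frac
    )
    mu_map = spec.mu_water_per_cm * body_frac
    if spec.lung_insert:
        # zero-activity, low-attenuation cylinder on the phantom axis
        rr = np.hypot(xs[:, None], ys[None, :])
        lung2d = (rr <= spec.lung_radius_mm).astype(np.float64)
        lung = lung2d[:, :, None] * frac_z[None, None, :]
        lung = np.minimum(lung, body_frac - sphere_frac)
        activity -= fp.background_concentration_kbq_ml * lung
        mu_map += (spec.lung_mu_per_cm - spec.mu_water_per_cm) * lung
    return VoxelPhantom(
        activity=np.ascontiguousarray(activity),
        mu_map=np.ascontiguousarray(np.maximum(mu_map, 0.0)),
        voxel_size_mm=float(voxel_size_mm),
        origin_mm=origin,
    )
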