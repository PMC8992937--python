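"""Shared fixtures.

The scaled-down study grid is 64 x 64 x 40 voxels at 4.8 mm (the 300 mm
torso outline needs the full 64-pixel transaxial extent); heavy
simulation fixtures are session-scoped so the noisy parameter sweep runs
once for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import spectiq as sq
from spectiq.nema import build_roi_layout
from spectiq.sweep import SweepConfig, run_parameter_sweep

GRID = (64, 64, 40)
VOXEL = 4.8


@pytest.fixture(scope="session")
def spec():
    return sq.default_phantom_spec()


@pytest.fixture(scope="session")
def phantom(spec):
    """Partial-volume (supersampled) phantom used for realistic simulation."""
    return sq.voxelize_phantom(spec, VOXEL, GRID, supersampling=4)


@pytest.fixture(scope="session")
def sharp_phantom(spec):
    """Binary-voxel phantom: ROI and sphere digitization coincide exactly."""
    return sq.voxelize_phantom(spec, VOXEL, GRID, supersampling=1)


@pytest.fixture(scope="session")
def layout(spec, phantom):
    return build_roi_layout(spec, phantom.shape, phantom.voxel_size_mm, phantom.origin_mm)


@pytest.fixture(scope="session")
def geometry(phantom):
    return sq.AcquisitionGeometry(matrix=(GRID[2], GRID[0]))


@pytest.fixture(scope="session")
def full_model(phantom, geometry):
    """Attenuation + collimator-blur system model on the study grid."""
    return sq.make_system_model(phantom, geometry, attenuation=True, blur=True)


@pytest.fixture(scope="session")
def calibrated(phantom, geometry, full_model):
    """(geometry with calibrated sensitivity, noise-free cps) at 1e6 counts/15 s."""
    unit = full_model.forward(phantom.activity)
    sens = sq.calibrate_sensitivity(unit, geometry.time_per_view_s, 1.0e6)
    geom = sq.AcquisitionGeometry(
        **{**geometry.__dict__, "sensitivity_cps": sens}
    )
    return geom, sens * unit


@pytest.fixture(scope="session")
def trend_sweep(phantom, spec, layout, calibrated):
    """Ten-seed study sweep at the operating grid (the heavy fixture)."""
    geom, noise_free = calibrated
    config = SweepConfig(
        durations_s=(3.0, 8.0, 15.0),
        iteration_grid=(4, 12, 24),
        n_subsets=8,
        fwhm_grid_mm=(0.0, 8.0),
        seeds=tuple(range(10)),
    )
    return run_parameter_sweep(
        phantom, noise_free, geom, config, layout, spec.ratio, n_gate_bins=15
    )
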