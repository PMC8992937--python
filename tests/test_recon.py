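"""OSEM correctness against hand and brute-force oracles; post-filter."""

import numpy as np
import pytest

from spectiq.acquisition import AcquisitionGeometry, ProjectionStack
from spectiq.exceptions import ConfigurationError, InvalidParameterError
from spectiq.projector import SystemModel
from spectiq.recon import (
    ReconParams,
    Volume,
    cylindrical_support,
    gaussian_postfilter_3d,
    osem,
    osem_iterations,
    subset_views,
)


class DenseSystem:
    """Toy projector from an explicit matrix: ray i is view i of shape (1, 1)."""

    def __init__(self, matrix: np.ndarray, vol_shape):
        self.A = np.asarray(matrix, dtype=float)
        self.n_views = self.A.shape[0]
        self.vol_shape = vol_shape

    def forward(self, vol, views):
        return (self.A[np.asarray(views)] @ np.ravel(vol)).reshape(-1, 1, 1)

    def back(self, projs, views):
        return (self.A[np.asarray(views)].T @ np.ravel(projs)).reshape(self.vol_shape)


def _run(data, model, iters, subsets, init):
    for x in osem_iterations(data.reshape(-1, 1, 1), model, iters, subsets, init):
        pass
    return x


class TestOsemOracles:
    def test_identity_system_fixed_point(self):
        """With an identity projector one MLEM update returns the data exactly."""
        model = DenseSystem(np.eye(4), (4,))
        y = np.array([3.0, 0.5, 7.0, 1.0])
        x = _run(y, model, 1, 1, np.ones(4))
        assert x == pytest.approx(y)

    def test_two_voxel_hand_update(self):
        """One MLEM step on A=[[1,0],[1,1]], y=(2,5), x0=(1,1).

        fp = (1, 2); ratio = (2, 2.5); A^T ratio = (4.5, 2.5);
        A^T 1 = (2, 1); x1 = (2.25, 2.5) by hand.
        """
        model = DenseSystem(np.array([[1.0, 0.0], [1.0, 1.0]]), (2,))
        x = _run(np.array([2.0, 5.0]), model, 1, 1, np.ones(2))
        assert x == pytest.approx([2.25, 2.5])

    def test_single_subset_matches_brute_force_mlem(self):
        """OSEM with 1 subset equals an independently coded MLEM on a 16x16 toy."""
        rng = np.random.default_rng(11)
        A = rng.random((16, 16))
        x_true = rng.random(16) + 0.1
        y = A @ x_true
        model = DenseSystem(A, (16,))
        ours = _run(y, model, 20, 1, np.ones(16))
        # brute-force oracle: textbook MLEM update, no shared code path
        x = np.ones(16)
        sens = A.sum(axis=0)
        for _ in range(20):
            x = x * (A.T @ (y / (A @ x))) / sens
        assert ours == pytest.approx(x, rel=1e-10)

    def test_every_subiteration_nonnegative(self):
        rng = np.random.default_rng(2)
        A = rng.random((12, 9))
        y = rng.poisson(5.0, size=12).astype(float)
        model = DenseSystem(A, (9,))
        for x in osem_iterations(y.reshape(-1, 1, 1), model, 6, 4, np.ones(9)):
            assert np.all(x >= 0)

    def test_poisson_loglikelihood_nondecreasing(self):
        """MLEM ascends the Poisson likelihood on a small matched problem."""
        rng = np.random.default_rng(8)
        A = rng.random((20, 10)) + 0.05
        y = rng.poisson(A @ (rng.random(10) * 4 + 1)).astype(float)
        model = DenseSystem(A, (10,))
        last = -np.inf
        for x in osem_iterations(y.reshape(-1, 1, 1), model, 15, 1, np.ones(10)):
            fp = A @ x
            ll = float((y * np.log(fp + 1e-300) - fp).sum())
            assert ll >= last - 1e-9
            last = ll

    def test_count_conservation_blur_only_model(self):
        """Total forward-projected counts equal data totals after each iteration."""
        n, nz = 32, 8
        m = SystemModel((n, n, nz), 4.8, np.arange(0, 360, 22.5), 250.0,
                        attenuation=False, blur=True)
        rng = np.random.default_rng(4)
        truth = np.zeros((n, n, nz))
        truth[12:20, 12:20, 2:6] = rng.random((8, 8, 4)) + 0.5
        y = rng.poisson(40 * m.forward(truth)).astype(float)
        init = np.where(cylindrical_support((n, n, nz)), 1.0, 0.0)
        for x in osem_iterations(y, m, 3, 1, init):
            assert m.forward(x).sum() == pytest.approx(y.sum(), rel=0.01)


class TestOsemApi:
    def _stack(self, counts, **geo):
        geom = AcquisitionGeometry(matrix=(counts.shape[1], counts.shape[2]), **geo)
        return ProjectionStack(counts=counts, geometry=geom, n_gate_bins=1,
                               bin_duration_s=15.0)

    def test_subsets_must_divide_views(self):
        with pytest.raises(ConfigurationError):
            subset_views(120, 7)

    def test_multibin_stack_rejected(self, phantom):
        geom = AcquisitionGeometry(matrix=(40, 64))
        counts = np.zeros((2, 120, 40, 64))
        stack = ProjectionStack(counts=counts, geometry=geom, n_gate_bins=2,
                                bin_duration_s=1.0)
        with pytest.raises(InvalidParameterError):
            osem(stack, phantom.mu_map, ReconParams())

    def test_all_zero_projections_warn_and_return_zero(self, phantom, full_model):
        counts = np.zeros((1, 120, 40, 64))
        stack = self._stack(counts)
        with pytest.warns(UserWarning):
            vol = osem(stack, phantom.mu_map, ReconParams(n_iterations=1),
                       model=full_model)
        assert vol.values.sum() == 0


class TestPostfilter:
    def test_zero_fwhm_is_identity(self):
        vol = Volume(values=np.random.default_rng(0).random((8, 8, 8)),
                     voxel_size_mm=4.8)
        assert gaussian_postfilter_3d(vol, 0.0) is vol

    def test_negative_fwhm_rejected(self):
        vol = Volume(values=np.ones((4, 4, 4)), voxel_size_mm=4.8)
        with pytest.raises(InvalidParameterError):
            gaussian_postfilter_3d(vol, -1.0)

    def test_impulse_response_width(self):
        """An 8 mm filter turns an impulse into an 8 mm FWHM Gaussian (+-5%)."""
        values = np.zeros((33, 33, 33))
        values[16, 16, 16] = 1.0
        out = gaussian_postfilter_3d(Volume(values=values, voxel_size_mm=4.8), 8.0)
        prof = out.values[:, 16, 16]
        half = prof.max() / 2.0
        above = np.where(prof >= half)[0]
        # parabolic-free estimate: interpolate the half crossings
        lo = above[0] - (prof[above[0]] - half) / (prof[above[0]] - prof[above[0] - 1])
        hi = above[-1] + (prof[above[-1]] - half) / (prof[above[-1]] - prof[above[-1] + 1])
        fwhm = (hi - lo) * 4.8
        assert fwhm == pytest.approx(8.0, rel=0.05)

    def test_uniform_volume_unchanged(self):
        vol = Volume(values=np.full((16, 16, 16), 3.3), voxel_size_mm=4.8)
        out = gaussian_postfilter_3d(vol, 12.0)
        assert out.values == pytest.approx(vol.values, rel=1e-12)

    def test_variance_nonincreasing_in_fwhm(self):
        rng = np.random.default_rng(6)
        vol = Volume(values=rng.random((24, 24, 24)), voxel_size_mm=4.8)
        variances = [
            gaussian_postfilter_3d(vol, f).values[6:18, 6:18, 6:18].var()
            for f in (0.0, 4.0, 8.0, 12.0)
        ]
        assert np.all(np.diff(variances) <= 0)
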