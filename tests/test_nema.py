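"""ROI layout rules and the RC / BV / CNR metric formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectiq.exceptions import InvalidParameterError, UndefinedMetricError
from spectiq.nema import (
    BACKGROUND_ROI_DIAMETER_MM,
    RoiStats,
    background_variability,
    circle_mask,
    circle_weights,
    cnr,
    contrast_recovery,
    evaluate_phantom_volume,
    evaluate_volume,
    rose_visible,
)


def _stats(c_hot=1.0, c_bkg=1.0, sd=0.1, sd_roi=0.1, k=60):
    return RoiStats(c_hot=c_hot, c_bkg=c_bkg, sd=sd, sd_roi=sd_roi, k=k)


class TestLayout:
    def test_twelve_positions_sixty_rois(self, layout):
        assert layout.background_centers_mm.shape == (12, 2)
        assert layout.n_background_rois == 60

    def test_sphere_roi_diameters_match_spheres(self, spec, layout):
        assert layout.roi_diameters_mm == spec.sphere_diameters_mm

    def test_margin_rules(self, spec, layout):
        """37 mm background ROIs stay 15 mm clear of the margin and spheres."""
        r = BACKGROUND_ROI_DIAMETER_MM / 2.0
        for c in layout.background_centers_mm:
            assert spec.body.margin_distance(c[0], c[1]) >= 15.0 + r - 1e-9
            for sc, d in zip(spec.sphere_centers_mm, spec.sphere_diameters_mm):
                assert np.linalg.norm(c - sc[:2]) >= 15.0 + r + d / 2.0 - 1e-9

    def test_analysis_slices_bracket_central(self, layout):
        c = layout.central_slice
        assert tuple(layout.analysis_slices) == (c - 2, c - 1, c, c + 1, c + 2)


class TestMetricFormulas:
    def test_perfect_recovery_is_100_percent(self):
        assert contrast_recovery(_stats(c_hot=8.5, c_bkg=1.0), 8.5) == pytest.approx(100.0)

    def test_zero_contrast_is_0_percent(self):
        assert contrast_recovery(_stats(c_hot=1.0, c_bkg=1.0), 8.5) == pytest.approx(0.0)

    def test_hand_evaluated_case(self):
        assert contrast_recovery(_stats(c_hot=5.675, c_bkg=1.0), 8.5) == pytest.approx(
            62.3333, abs=1e-3
        )

    def test_ratio_must_exceed_one(self):
        with pytest.raises(InvalidParameterError):
            contrast_recovery(_stats(), 1.0)

    def test_zero_background_undefined(self):
        with pytest.raises(UndefinedMetricError):
            contrast_recovery(_stats(c_bkg=0.0), 8.5)
        with pytest.raises(UndefinedMetricError):
            background_variability(_stats(c_bkg=0.0))
        with pytest.raises(UndefinedMetricError):
            cnr(_stats(sd_roi=0.0))

    def test_two_point_background_variability(self):
        """Background means {9, 11}: sample SD = sqrt(2), BV = 14.14%."""
        sd = float(np.std([9.0, 11.0], ddof=1))
        assert sd == pytest.approx(math.sqrt(2.0))
        assert background_variability(_stats(c_bkg=10.0, sd=sd, k=2)) == pytest.approx(
            14.142, abs=1e-3
        )

    def test_bv_scale_invariant(self):
        a = background_variability(_stats(c_bkg=10.0, sd=1.5))
        b = background_variability(_stats(c_bkg=20.0, sd=3.0))
        assert a == pytest.approx(b)

    def test_cnr_boundary_is_not_visible(self):
        """CNR exactly 5 fails the strict Rose criterion."""
        value = cnr(_stats(c_hot=11.0, c_bkg=1.0, sd_roi=2.0))
        assert value == pytest.approx(5.0)
        assert not rose_visible(value)
        assert rose_visible(np.nextafter(5.0, 6.0))

    @given(st.lists(st.floats(0.1, 100.0), min_size=2, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_sample_sd_matches_two_pass_oracle(self, means):
        """The K-1 denominator SD agrees with a brute-force two-pass oracle."""
        arr = np.asarray(means)
        mean = sum(means) / len(means)
        oracle = math.sqrt(sum((m - mean) ** 2 for m in means) / (len(means) - 1))
        assert float(arr.std(ddof=1)) == pytest.approx(oracle, rel=1e-9, abs=1e-12)


class TestRoiMasks:
    @pytest.mark.parametrize("diameter", [10.0, 13.0, 17.0, 22.0, 28.0, 37.0])
    def test_center_rule_consistent_with_supersampled_oracle(self, layout, diameter):
        """Centre membership agrees with the fractional-area oracle on every
        interior and exterior pixel, and its total area deviates by no more
        than the boundary-straddling pixel area."""
        vox = 4.8
        origin = (-32 * vox, -32 * vox)
        centers = list(layout.background_centers_mm) + list(layout.sphere_centers_mm)
        for c in centers:
            mask = circle_mask((64, 64), vox, origin, tuple(c), diameter)
            area = circle_weights((64, 64), vox, origin, tuple(c), diameter, "area")
            assert mask[area >= 1.0].all()
            assert not mask[area <= 0.0].any()
            n_straddle = ((area > 0) & (area < 1)).sum()
            assert abs(mask.sum() - area.sum()) <= n_straddle


class TestEvaluateVolume:
    def test_ground_truth_phantom_full_recovery(self, spec, sharp_phantom, layout):
        """On the sharp digital phantom the ROI analysis returns RC = 100%."""
        res = evaluate_phantom_volume(sharp_phantom, layout, spec.ratio)
        for r in res:
            assert r.rc_percent == pytest.approx(100.0, abs=0.5)
            assert r.bv_percent == pytest.approx(0.0, abs=1e-9)

    def test_uniform_volume_zero_metrics(self, spec, layout, phantom):
        vol = np.full(phantom.shape, 2.0)
        res = evaluate_volume(vol, layout, spec.ratio, phantom.voxel_size_mm,
                              phantom.origin_mm)
        for r in res:
            assert r.rc_percent == pytest.approx(0.0)
            assert r.bv_percent == pytest.approx(0.0)
            assert not r.rose_visible

    def test_metrics_invariant_under_positive_scaling(self, spec, layout, phantom):
        rng = np.random.default_rng(12)
        vol = phantom.activity + rng.random(phantom.shape)
        a = evaluate_volume(vol, layout, spec.ratio, phantom.voxel_size_mm,
                            phantom.origin_mm)
        b = evaluate_volume(3.7 * vol, layout, spec.ratio, phantom.voxel_size_mm,
                            phantom.origin_mm)
        for ra, rb in zip(a, b):
            assert ra.rc_percent == pytest.approx(rb.rc_percent, rel=1e-9)
            assert ra.bv_percent == pytest.approx(rb.bv_percent, rel=1e-9)
            assert ra.cnr == pytest.approx(rb.cnr, rel=1e-9)
            assert ra.rose_visible == rb.rose_visible
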