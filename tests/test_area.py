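"""Area pipeline: binarization, hole filling, component selection,
calibration, and the pixel-to-mm^2 conversion."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splintleaf.area import (CalibrationError, OracleModel, binarize,
                             calibration_pixels, compute_area, fill_holes,
                             largest_component, measure, measurement_error)
from splintleaf.synthetic import (GeneratorParams, apply_method_artifacts,
                                  generate_leaf)


class TestBinarize:
    def test_above_threshold_all_foreground(self):
        assert binarize(np.full((3, 3), 0.9), 0.5).sum() == 9

    def test_tie_goes_to_foreground(self):
        assert binarize(np.full((3, 3), 0.5), 0.5).sum() == 9

    def test_monotone_in_threshold(self, rng):
        prob = rng.random((16, 16))
        counts = [binarize(prob, t).sum() for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_threshold_bounds_enforced(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), 1.0)


class TestFillHoles:
    def test_single_pixel_hole_filled(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[1:4, 1:4] = 1
        m[2, 2] = 0
        assert m.sum() == 8
        assert fill_holes(m).sum() == 9

    def test_hole_free_mask_unchanged(self, small_sample):
        m = small_sample.unoccluded_mask
        assert np.array_equal(fill_holes(m), m)

    def test_border_notch_not_filled(self):
        """Background 4-connected to the border must stay background."""
        m = np.ones((5, 5), dtype=np.uint8)
        m[0:3, 2] = 0   # slot open to the top border
        assert np.array_equal(fill_holes(m), m)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_fixed_point_matches_border_floodfill_oracle(self, seed):
        """fill_holes equals the complement of a border flood fill, and is
        idempotent."""
        rng = np.random.default_rng(seed)
        m = (rng.random((12, 12)) > 0.55).astype(np.uint8)
        filled = fill_holes(m)
        # oracle: BFS flood fill of the background from the border (4-conn)
        bg = m == 0
        reach = np.zeros_like(bg)
        stack = [(r, c) for r in range(12) for c in range(12)
                 if bg[r, c] and (r in (0, 11) or c in (0, 11))]
        for r, c in stack:
            reach[r, c] = True
        while stack:
            r, c = stack.pop()
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= rr < 12 and 0 <= cc < 12 and bg[rr, cc] and not reach[rr, cc]:
                    reach[rr, cc] = True
                    stack.append((rr, cc))
        oracle = (~reach).astype(np.uint8)
        assert np.array_equal(filled, oracle)
        assert np.array_equal(fill_holes(filled), filled)
        assert (filled >= m).all()   # foreground never shrinks


class TestLargestComponent:
    def test_keeps_largest_of_two(self):
        m = np.zeros((20, 20), dtype=np.uint8)
        m[1:11, 1:11] = 1          # 100 px
        m[15:16, 15:18] = 1        # 3 px
        out, empty = largest_component(m)
        assert not empty
        assert out.sum() == 100
        assert out[15, 15] == 0

    def test_single_component_unchanged(self, small_sample):
        out, empty = largest_component(small_sample.unoccluded_mask)
        assert not empty
        assert np.array_equal(out, small_sample.unoccluded_mask)

    def test_empty_mask_flagged(self):
        out, empty = largest_component(np.zeros((4, 4), dtype=np.uint8))
        assert empty and out.sum() == 0

    def test_tie_keeps_raster_first_component(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[1:3, 1:3] = 1   # first in raster order
        m[6:8, 6:8] = 1   # same size
        out, _ = largest_component(m)
        assert out[1, 1] == 1 and out[6, 6] == 0

    def test_diagonal_pixels_are_one_component(self):
        m = np.zeros((4, 4), dtype=np.uint8)
        m[0, 0] = m[1, 1] = 1   # 8-connectivity joins diagonals
        out, _ = largest_component(m)
        assert out.sum() == 2


class TestCalibration:
    def test_synthetic_marker_counted_exactly(self, default_sample):
        n = calibration_pixels(default_sample.image)
        assert n == default_sample.calibration_pixel_count == 400

    def test_explicit_region_half_open(self):
        img = np.zeros((20, 20, 3), dtype=np.uint8)
        assert calibration_pixels(img, region=(0, 0, 10, 10)) == 100

    def test_region_out_of_bounds_rejected(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(CalibrationError):
            calibration_pixels(img, region=(0, 0, 11, 5))

    def test_no_marker_fails_loudly(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(CalibrationError, match="region"):
            calibration_pixels(img)

    def test_jitter_beyond_tolerance_fails(self, default_sample):
        img = default_sample.image.copy()
        r0, c0, r1, c1 = default_sample.calibration_region
        sq = img[r0:r1, c0:c1].astype(np.int32)
        img[r0:r1, c0:c1] = np.clip(sq - 40, 0, 255)   # heavy color shift
        with pytest.raises(CalibrationError):
            calibration_pixels(img, tolerance=10)


class TestComputeArea:
    def test_direct_arithmetic(self):
        assert compute_area(2000, 500, 25.0) == pytest.approx(100.0)

    def test_identity_when_counts_equal(self):
        assert compute_area(400, 400, 25.0) == pytest.approx(25.0)

    def test_scale_invariance(self):
        assert compute_area(2000, 500, 25.0) == compute_area(4000, 1000, 25.0)

    @pytest.mark.parametrize("args", [(0, 1, 25.0), (1, 0, 25.0), (1, 1, 0.0)])
    def test_nonpositive_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            compute_area(*args)


class TestMeasurementError:
    def test_negative_five_percent(self):
        r = measurement_error(100.0, 95.0)
        assert r.abs_error_pct == pytest.approx(5.0)
        assert r.signed_error_pct == pytest.approx(-5.0)

    def test_exact_measurement(self):
        r = measurement_error(100.0, 100.0)
        assert r.abs_error_pct == 0.0

    def test_positive_error_direct_arithmetic(self):
        r = measurement_error(50.0, 56.06)
        assert r.abs_error_pct == pytest.approx(12.12)
        assert r.signed_error_pct == pytest.approx(12.12)

    def test_nonpositive_standard_rejected(self):
        with pytest.raises(ValueError):
            measurement_error(0.0, 10.0)

    def test_abs_bounds_signed(self, rng):
        for _ in range(20):
            r = measurement_error(rng.uniform(10, 100), rng.uniform(10, 100))
            assert r.abs_error_pct >= abs(r.signed_error_pct) - 1e-12


class TestMeasurePipeline:
    def test_oracle_on_splint_sample_within_two_percent(self, default_sample):
        s = default_sample
        m = measure(s.image, OracleModel(s.mask),
                    calib_area_mm2=s.calibration_area_mm2)
        rel = abs(m.leaf_area_mm2 - s.true_area_mm2) / s.true_area_mm2
        assert rel <= 0.02

    def test_stretching_oracle_biases_negative(self, default_sample):
        s = apply_method_artifacts(default_sample, "stretching")
        m = measure(s.image, OracleModel(s.mask),
                    calib_area_mm2=s.calibration_area_mm2)
        assert m.leaf_area_mm2 < s.true_area_mm2

    def test_measure_is_deterministic(self, default_sample):
        s = default_sample
        a = measure(s.image, OracleModel(s.mask))
        b = measure(s.image, OracleModel(s.mask))
        assert a == b

    def test_intermediate_counts_logged(self, default_sample):
        s = default_sample
        logged = []
        measure(s.image, OracleModel(s.mask), log=logged.append)
        assert logged and {"binarized_px", "filled_px", "leaf_px",
                           "calibration_px"} <= set(logged[0])

    def test_scale_invariance_under_resampling(self):
        """Upsampling the frame 2x changes PNL and PNC by the same factor,
        leaving LA within 3%."""
        from skimage.transform import resize
        s = generate_leaf(GeneratorParams(seed=3))
        m1 = measure(s.image, OracleModel(s.mask),
                     calib_area_mm2=s.calibration_area_mm2)
        img2 = (resize(s.image, (256, 256), order=0,
                       preserve_range=True)).astype(np.uint8)
        mask2 = resize(s.mask, (256, 256), order=0,
                       preserve_range=True).astype(np.uint8)
        m2 = measure(img2, OracleModel(mask2),
                     calib_area_mm2=s.calibration_area_mm2)
        assert m2.leaf_area_mm2 == pytest.approx(m1.leaf_area_mm2, rel=0.03)

    def test_rasterization_error_below_one_percent_for_big_leaves(self):
        """With perfect masks the only error is rasterization: < 1% for
        leaves of at least 2000 px."""
        for seed in range(20):
            s = generate_leaf(GeneratorParams(seed=seed))
            assert s.unoccluded_mask.sum() >= 2000
            m = measure(s.image, OracleModel(s.unoccluded_mask),
                        calib_area_mm2=s.calibration_area_mm2)
            rel = abs(m.leaf_area_mm2 - s.true_area_mm2) / s.true_area_mm2
            assert rel < 0.01, f"seed {seed}: {rel:.4f}"
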