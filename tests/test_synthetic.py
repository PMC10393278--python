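"""Synthetic leaf generator: determinism, ground-truth consistency,
method artifacts, and dataset splitting."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splintleaf.synthetic import (CALIBRATION_COLOR, GenerationError,
                                  GeneratorParams, apply_method_artifacts,
                                  generate_dataset, generate_leaf,
                                  rasterize_polygon, shoelace_area,
                                  split_sizes)

SMALL = dict(image_height=64, image_width=64, mm_per_pixel=0.5,
             leaf_area_range_mm2=(100.0, 250.0))


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        dict(image_height=32),
        dict(mm_per_pixel=0.0),
        dict(leaf_area_range_mm2=(300.0, 200.0)),
        dict(treatment="bogus"),
        dict(method="bogus"),
        dict(illumination="dawn"),
        dict(mm_per_pixel=0.01),   # calibration square larger than frame
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorParams(**kwargs)


class TestGenerateLeaf:
    def test_bit_identical_for_fixed_seed(self):
        a = generate_leaf(GeneratorParams(seed=7))
        b = generate_leaf(GeneratorParams(seed=7))
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)
        assert a.true_area_mm2 == b.true_area_mm2

    def test_true_area_equals_pixel_count_times_scale(self, small_sample):
        p = small_sample.metadata
        assert small_sample.true_area_mm2 == pytest.approx(
            small_sample.unoccluded_mask.sum() * p.mm_per_pixel ** 2)

    def test_rasterized_area_matches_shoelace_oracle(self):
        """Mask pixel count agrees with the analytic polygon area within 2%
        across 100 seeded shapes."""
        for seed in range(100):
            s = generate_leaf(GeneratorParams(seed=seed))
            analytic = shoelace_area(s.outline_xy)
            raster = float(s.unoccluded_mask.sum())
            assert abs(raster - analytic) / analytic <= 0.02, f"seed {seed}"

    def test_single_connected_component(self, small_sample):
        from scipy import ndimage
        _, n = ndimage.label(small_sample.unoccluded_mask)
        assert n == 1

    def test_treatment_changes_color_not_shape(self):
        base = dict(SMALL, seed=5)
        ck = generate_leaf(GeneratorParams(treatment="CK", **base))
        nd = generate_leaf(GeneratorParams(treatment="N_def", **base))
        assert np.array_equal(ck.mask, nd.mask)
        assert not np.array_equal(ck.image, nd.image)

    def test_calibration_square_pixel_count(self, default_sample):
        p = default_sample.metadata
        side = p.calibration_side_mm / p.mm_per_pixel
        assert default_sample.calibration_pixel_count == pytest.approx(
            side ** 2, abs=2 * side + 1)   # one boundary row/column tolerance
        r0, c0, r1, c1 = default_sample.calibration_region
        sq = default_sample.image[r0:r1, c0:c1]
        assert (sq == CALIBRATION_COLOR).all()

    def test_calibration_never_overlaps_leaf(self):
        for seed in range(30):
            s = generate_leaf(GeneratorParams(seed=seed))
            r0, c0, r1, c1 = s.calibration_region
            assert not s.unoccluded_mask[r0:r1, c0:c1].any()

    def test_night_darkens_background(self):
        base = dict(SMALL, seed=5)
        day = generate_leaf(GeneratorParams(illumination="day", **base))
        night = generate_leaf(GeneratorParams(illumination="night", **base))
        bg = day.unoccluded_mask == 0
        assert night.image[bg].mean() < day.image[bg].mean()

    def test_impossible_placement_raises(self):
        with pytest.raises(GenerationError):
            generate_leaf(GeneratorParams(
                image_height=64, image_width=64, mm_per_pixel=0.5,
                leaf_area_range_mm2=(2000.0, 2100.0), seed=0))


class TestMethodArtifacts:
    def test_splint_is_identity_on_mask(self, small_sample):
        out = apply_method_artifacts(small_sample, "splint")
        assert np.array_equal(out.mask, out.unoccluded_mask)

    def test_stretching_strictly_removes_pixels(self, small_sample):
        out = apply_method_artifacts(small_sample, "stretching")
        assert out.mask.sum() < out.unoccluded_mask.sum()
        assert out.true_area_mm2 == small_sample.true_area_mm2

    def test_zero_clip_size_is_identity(self, small_params):
        p = dataclasses.replace(small_params, clip_size_px=0.0)
        s = generate_leaf(p)
        out = apply_method_artifacts(s, "stretching")
        assert np.array_equal(out.mask, s.unoccluded_mask)
        assert np.array_equal(out.image, s.image)

    def test_occlusion_monotone_in_clip_size(self, small_params):
        counts = []
        for size in (0.0, 2.0, 4.0, 6.0):
            p = dataclasses.replace(small_params, clip_size_px=size)
            out = apply_method_artifacts(generate_leaf(p), "stretching")
            counts.append(int(out.mask.sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_manual_inflates_observed_silhouette(self, default_sample):
        out = apply_method_artifacts(default_sample, "manual")
        assert out.mask.sum() > out.unoccluded_mask.sum()
        assert out.true_area_mm2 == default_sample.true_area_mm2

    def test_unknown_method_rejected(self, small_sample):
        with pytest.raises(ValueError):
            apply_method_artifacts(small_sample, "laser")


class TestRasterization:
    def test_axis_aligned_square_exact(self):
        # pixel centers (c, r) strictly inside (0.5..9.5)^2 -> 9x9 pixels
        poly = np.array([[0.5, 0.5], [9.5, 0.5], [9.5, 9.5], [0.5, 9.5]])
        mask = rasterize_polygon(poly, 12, 12)
        assert mask.sum() == 81

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_random_polygon_matches_shoelace(self, seed):
        rng = np.random.default_rng(seed)
        theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        r = 15 + 5 * np.cos(rng.integers(2, 5) * theta + rng.uniform(0, 6))
        poly = np.column_stack([32 + r * np.cos(theta), 32 + r * np.sin(theta)])
        mask = rasterize_polygon(poly, 64, 64)
        analytic = shoelace_area(poly)
        assert abs(mask.sum() - analytic) / analytic <= 0.02


class TestDataset:
    def test_paper_scale_split_sizes(self):
        assert split_sizes(1080, (0.6, 0.2, 0.2)) == (648, 216, 216)

    def test_tiny_split_sizes(self):
        assert split_sizes(10, (0.6, 0.2, 0.2)) == (6, 2, 2)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            split_sizes(10, (0.5, 0.2, 0.2))

    def test_manifest_and_determinism(self, tmp_path):
        p = GeneratorParams(**SMALL)
        m1 = generate_dataset(10, p, tmp_path / "a", seed=3)
        m2 = generate_dataset(10, p, tmp_path / "b", seed=3)
        assert list(m1["split"]) == list(m2["split"])
        assert m1["true_area_mm2"].tolist() == m2["true_area_mm2"].tolist()
        assert sorted(m1["split"].value_counts().to_dict().items()) == [
            ("test", 2), ("train", 6), ("val", 2)]
        assert (tmp_path / "a" / "manifest.csv").exists()
        assert len(list((tmp_path / "a" / "images").glob("*.png"))) == 10

    def test_treatments_cycle_round_robin(self, tmp_path):
        p = GeneratorParams(**SMALL)
        m = generate_dataset(10, p, tmp_path / "c", seed=0)
        assert m["treatment"].nunique() == 5

    def test_too_small_n_rejected(self, tmp_path):
        with pytest.raises(GenerationError):
            generate_dataset(3, GeneratorParams(**SMALL), tmp_path / "d")
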