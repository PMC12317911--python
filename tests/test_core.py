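"""Unit and property tests for the per-slice image computations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from batcsi.core import (
    ConversionSpec,
    ExtractionSpec,
    RatioMatrix,
    RatioPolicy,
    RawImageMatrix,
    RoiMask,
    apply_roi,
    extract_brown_fat,
    make_roi_mask,
    overlay_contours,
    render_ratio_image,
    rescale_intensity,
    water_oil_ratio,
)
from conftest import full_mask, make_pair


class TestRescaleIntensity:
    def test_upper_bound_maps_to_255(self):
        out = rescale_intensity(np.array([[4095]]), ConversionSpec(0, 4095))
        assert out[0, 0] == 255

    def test_lower_bound_maps_to_0(self):
        assert rescale_intensity(np.array([[0]]), ConversionSpec(0, 4095))[0, 0] == 0

    def test_midpoint(self):
        # independent arithmetic: 2048/4095*255 = 127.5329...; rounds to 128
        expected = math.floor(2048 / 4095 * 255 + 0.5)
        assert expected == 128
        out = rescale_intensity(np.array([[2048]]), ConversionSpec(0, 4095))
        assert out[0, 0] == expected

    def test_full_range_yields_256_distinct_levels(self):
        out = rescale_intensity(np.arange(4096), ConversionSpec(0, 4095))
        assert len(np.unique(out)) == 256
        assert out.min() == 0 and out.max() == 255

    def test_monotone_nondecreasing_over_full_range(self):
        out = rescale_intensity(np.arange(4096), ConversionSpec(0, 4095))
        assert np.all(np.diff(out.astype(int)) >= 0)

    def test_degenerate_spec_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ConversionSpec(5, 5)

    def test_out_of_range_clipped(self):
        out = rescale_intensity(np.array([[5000.0, -3.0]]), ConversionSpec(0, 4095))
        assert out[0, 0] == 255 and out[0, 1] == 0

    @given(
        st.lists(st.integers(min_value=0, max_value=4095), min_size=2, max_size=50)
    )
    @settings(max_examples=50, deadline=None)
    def test_monotonicity_property(self, values):
        values = sorted(values)
        out = rescale_intensity(np.array(values), ConversionSpec(0, 4095))
        assert np.all(np.diff(out.astype(int)) >= 0)
        assert out.min() >= 0 and out.max() <= 255


class TestWaterOilRatio:
    def test_identity_ratio(self):
        w, f = make_pair([[10, 20], [30, 40]], [[10, 20], [30, 40]])
        r = water_oil_ratio(w, f)
        np.testing.assert_array_equal(r.values, 1.0)
        assert r.provenance == "full"

    def test_direct_quotient(self):
        w, f = make_pair([[50]], [[25]])
        assert water_oil_ratio(w, f).values[0, 0] == 2.0

    def test_zero_fat_capped(self):
        w, f = make_pair([[7]], [[0]])
        r = water_oil_ratio(w, f, RatioPolicy(zero_fat_cap=1000))
        assert r.values[0, 0] == 1000
        assert r.n_capped == 1

    def test_zero_zero_is_zero(self):
        w, f = make_pair([[0]], [[0]])
        r = water_oil_ratio(w, f)
        assert r.values[0, 0] == 0.0
        assert r.n_capped == 0

    def test_shape_mismatch_rejected(self):
        w, _ = make_pair([[1, 2]], [[1, 2]])
        _, f = make_pair([[1]], [[1]])
        with pytest.raises(ValueError, match="shape mismatch"):
            water_oil_ratio(w, f)

    def test_swapped_channels_rejected(self):
        w, f = make_pair([[1]], [[1]])
        with pytest.raises(ValueError, match="channel"):
            water_oil_ratio(f, w)

    def test_reciprocal_property(self, rng):
        # ratio(w, f) * ratio(f, w) == 1 wherever both signals positive
        wv = rng.integers(1, 4096, (16, 16))
        fv = rng.integers(1, 4096, (16, 16))
        w = RawImageMatrix(wv, "water")
        f = RawImageMatrix(fv, "fat")
        w2 = RawImageMatrix(fv, "water")
        f2 = RawImageMatrix(wv, "fat")
        prod = water_oil_ratio(w, f).values * water_oil_ratio(w2, f2).values
        np.testing.assert_allclose(prod, 1.0)


class TestApplyRoi:
    def test_all_true_mask_is_identity(self, rng):
        r = RatioMatrix(rng.random((8, 8)))
        out = apply_roi(r, full_mask((8, 8)))
        np.testing.assert_array_equal(out.values, r.values)
        assert out.provenance == "roi_masked"

    def test_all_false_mask_zeroes(self, rng):
        r = RatioMatrix(rng.random((8, 8)))
        out = apply_roi(r, RoiMask(np.zeros((8, 8), dtype=bool)))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_checkerboard_matches_bruteforce(self, rng):
        vals = rng.random((10, 10))
        r = RatioMatrix(vals)
        board = np.indices((10, 10)).sum(axis=0) % 2 == 0
        out = apply_roi(r, RoiMask(board))
        # brute-force elementwise oracle
        expected = np.empty_like(vals)
        for i in range(10):
            for j in range(10):
                expected[i, j] = vals[i, j] if board[i, j] else 0.0
        np.testing.assert_array_equal(out.values, expected)

    def test_masking_is_idempotent(self, rng):
        vals = rng.random((12, 12))
        mask = RoiMask(rng.random((12, 12)) > 0.5)
        once = apply_roi(RatioMatrix(vals), mask)
        twice = apply_roi(RatioMatrix(once.values, "full"), mask)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            apply_roi(RatioMatrix(np.ones((2, 2))), RoiMask(np.ones((3, 3), bool)))


class TestExtractBrownFat:
    def _masked(self, vals, mask):
        return apply_roi(RatioMatrix(np.asarray(vals, dtype=float)), mask)

    def test_top_one_percent_of_1000_distinct(self, rng):
        vals = rng.permutation(1000).astype(float).reshape(25, 40) + 1.0
        mask = full_mask((25, 40))
        prwo = self._masked(vals, mask)
        bprwo, retained = extract_brown_fat(prwo, mask, ExtractionSpec(0.01))
        assert len(retained) == 10
        top10 = np.sort(vals.ravel())[-10:]
        kept = np.sort(bprwo.values[bprwo.values > 0])
        np.testing.assert_array_equal(kept, top10)

    def test_full_retention_is_identity(self, rng):
        vals = rng.random((10, 10))
        mask = full_mask((10, 10))
        prwo = self._masked(vals, mask)
        bprwo, retained = extract_brown_fat(prwo, mask, ExtractionSpec(1.0))
        np.testing.assert_array_equal(bprwo.values, prwo.values)
        assert len(retained) == 100

    def test_all_equal_ties_broken_row_major(self):
        # 200 equal in-ROI values, 1% -> k = 2, smallest row-major indices win
        mask = full_mask((10, 20))
        prwo = self._masked(np.full((10, 20), 5.0), mask)
        _, retained = extract_brown_fat(prwo, mask, ExtractionSpec(0.01))
        assert retained == [(0, 0), (0, 1)]

    def test_stable_sort_oracle_with_ties(self, rng):
        vals = rng.integers(0, 5, (12, 12)).astype(float) + 1.0
        mask = RoiMask(rng.random((12, 12)) > 0.3)
        prwo = self._masked(vals, mask)
        spec = ExtractionSpec(0.07)
        _, retained = extract_brown_fat(prwo, mask, spec)
        # oracle: stable sort of in-ROI (value desc, row-major asc), take k
        items = [
            (-prwo.values[i, j], i * 12 + j, (i, j))
            for i in range(12)
            for j in range(12)
            if mask.in_roi[i, j]
        ]
        items.sort()
        k = math.ceil(0.07 * mask.n_in_roi)
        assert retained == [t[2] for t in items[:k]]

    def test_support_size_is_exactly_k(self, rng):
        vals = rng.random((20, 20))
        mask = RoiMask(rng.random((20, 20)) > 0.4)
        prwo = self._masked(vals, mask)
        bprwo, retained = extract_brown_fat(prwo, mask, ExtractionSpec(0.05))
        k = math.ceil(0.05 * mask.n_in_roi)
        assert len(retained) == k
        assert int(np.count_nonzero(bprwo.values)) == k

    def test_sum_equals_k_largest(self, rng):
        vals = rng.random((15, 15))
        mask = RoiMask(rng.random((15, 15)) > 0.5)
        prwo = self._masked(vals, mask)
        bprwo, retained = extract_brown_fat(prwo, mask, ExtractionSpec(0.03))
        in_roi = np.sort(prwo.values[mask.in_roi])[::-1]
        np.testing.assert_allclose(
            bprwo.values.sum(), in_roi[: len(retained)].sum()
        )

    def test_invariant_to_out_of_roi_values(self, rng):
        vals = rng.random((10, 10))
        mask = RoiMask(rng.random((10, 10)) > 0.5)
        prwo = self._masked(vals, mask)
        _, retained1 = extract_brown_fat(prwo, mask)
        shuffled = vals.copy()
        shuffled[~mask.in_roi] = rng.permutation(shuffled[~mask.in_roi])
        _, retained2 = extract_brown_fat(self._masked(shuffled, mask), mask)
        assert retained1 == retained2

    def test_empty_roi_rejected(self):
        prwo = RatioMatrix(np.zeros((4, 4)), "roi_masked")
        with pytest.raises(ValueError, match="empty ROI"):
            extract_brown_fat(prwo, RoiMask(np.zeros((4, 4), bool)))

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="retain_fraction"):
            ExtractionSpec(0.0)
        with pytest.raises(ValueError, match="retain_fraction"):
            ExtractionSpec(1.5)

    def test_unmasked_input_rejected(self, rng):
        r = RatioMatrix(rng.random((4, 4)))
        with pytest.raises(ValueError, match="ROI-masked"):
            extract_brown_fat(r, full_mask((4, 4)))

    def test_deterministic(self, rng):
        vals = rng.random((10, 10))
        mask = RoiMask(rng.random((10, 10)) > 0.5)
        a = extract_brown_fat(self._masked(vals, mask), mask)
        b = extract_brown_fat(self._masked(vals, mask), mask)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        assert a[1] == b[1]


class TestRenderRatioImage:
    def test_max_maps_to_255(self):
        r = RatioMatrix(np.array([[0.0, 3.7], [1.0, 2.0]]))
        out = render_ratio_image(r)
        assert out[0, 1] == 255 and out[0, 0] == 0

    def test_constant_renders_all_zero(self):
        out = render_ratio_image(RatioMatrix(np.full((3, 3), 7.0)))
        np.testing.assert_array_equal(out, 0)

    def test_two_value_matrix(self):
        out = render_ratio_image(RatioMatrix(np.array([[0.0, 10.0]])))
        np.testing.assert_array_equal(out, [[0, 255]])


class TestOverlayContours:
    def test_empty_contours_triplicate(self, rng):
        img = rng.integers(0, 256, (5, 5)).astype(np.uint8)
        out = overlay_contours(img, RoiMask(np.ones((5, 5), bool)))
        assert out.shape == (5, 5, 3)
        for ch in range(3):
            np.testing.assert_array_equal(out[..., ch], img)

    def test_single_pixel_outer(self):
        img = np.full((4, 4), 100, dtype=np.uint8)
        mask = RoiMask(np.ones((4, 4), bool), outer_contour=((2, 3),))
        out = overlay_contours(img, mask)
        np.testing.assert_array_equal(out[2, 3], [0, 255, 0])
        assert (out[..., 1] == 255).sum() == 1

    def test_phantom_mask_green_set_equals_outer_path(self, small_params):
        from batcsi.phantom import generate_phantom_slice

        water, fat, mask = generate_phantom_slice(small_params)
        img = np.zeros(mask.shape, dtype=np.uint8)
        out = overlay_contours(img, mask)
        green = set(zip(*np.nonzero((out[..., 1] == 255) & (out[..., 0] == 0))))
        assert green == set(mask.outer_contour)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            overlay_contours(np.zeros((2, 2), np.uint8), RoiMask(np.ones((3, 3), bool)))


class TestRoiMaskTracing:
    def test_annulus_has_inner_and_outer(self, small_params):
        from batcsi.phantom import generate_phantom_slice

        _, _, mask = generate_phantom_slice(small_params)
        assert len(mask.outer_contour) > 0
        assert len(mask.inner_contour) > 0
        for r, c in mask.outer_contour + mask.inner_contour:
            assert mask.in_roi[r, c]

    def test_solid_disk_has_no_inner_contour(self):
        rr, cc = np.ogrid[:20, :20]
        disk = (rr - 10) ** 2 + (cc - 10) ** 2 <= 36
        mask = make_roi_mask(disk)
        assert mask.inner_contour == ()
        assert len(mask.outer_contour) > 0
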