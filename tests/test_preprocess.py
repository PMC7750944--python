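"""Upsampling, coordinate mapping, seed rendering, cross dilation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import beadspot as bs
from beadspot.preprocess import UpsampleSpec, factor_for_diameter_range


def bilinear_oracle(image: np.ndarray, factor: int) -> np.ndarray:
    """Closed-form bilinear interpolant under pixel-area alignment with
    edge clamping; the independent reference for upsample_bilinear."""
    h, w = image.shape
    out = np.zeros((factor * h, factor * w))
    for i in range(factor * h):
        for j in range(factor * w):
            r = min(max((i - (factor - 1) / 2) / factor, 0), h - 1)
            c = min(max((j - (factor - 1) / 2) / factor, 0), w - 1)
            r0, c0 = int(np.floor(r)), int(np.floor(c))
            r1, c1 = min(r0 + 1, h - 1), min(c0 + 1, w - 1)
            fr, fc = r - r0, c - c0
            out[i, j] = (
                image[r0, c0] * (1 - fr) * (1 - fc)
                + image[r1, c0] * fr * (1 - fc)
                + image[r0, c1] * (1 - fr) * fc
                + image[r1, c1] * fr * fc
            )
    return out


class TestNormalize:
    def test_constant_image_maps_to_zeros(self):
        np.testing.assert_array_equal(
            bs.normalize_intensity(np.full((5, 5), 37.0)), np.zeros((5, 5))
        )

    def test_output_spans_unit_interval(self, rng):
        img = rng.integers(100, 5000, size=(50, 50)).astype(np.uint16)
        out = bs.normalize_intensity(img)
        assert out.min() == 0.0 and out.max() == 1.0
        # interior values follow the 1/99-percentile linear map
        lo, hi = np.percentile(img, [1, 99])
        mid = img[25, 25]
        assert out[25, 25] == pytest.approx(np.clip((mid - lo) / (hi - lo), 0, 1))

    def test_robust_to_single_hot_pixel(self, rng):
        img = rng.random((40, 40))
        img[3, 3] = 1e6
        out = bs.normalize_intensity(img)
        assert np.median(out) > 0.1  # hot pixel did not crush the range


class TestUpsample:
    def test_factor_one_is_identity(self, rng):
        img = rng.random((6, 9))
        np.testing.assert_array_equal(bs.upsample_bilinear(img, UpsampleSpec(1)), img)

    def test_constant_stays_constant(self):
        img = np.full((4, 4), 0.3)
        out = bs.upsample_bilinear(img, UpsampleSpec(4))
        assert out.shape == (16, 16)
        np.testing.assert_allclose(out, 0.3)

    @pytest.mark.parametrize("factor", [2, 3, 4])
    def test_agrees_with_closed_form_interpolant(self, rng, factor):
        img = rng.random((5, 7))
        out = bs.upsample_bilinear(img, UpsampleSpec(factor))
        np.testing.assert_allclose(out, bilinear_oracle(img, factor), atol=1e-12)

    def test_block_centers_reproduce_original_values(self, rng):
        # pixel-area alignment: the center of each factor x factor block
        # samples the original pixel exactly
        img = rng.random((3, 3))
        out = bs.upsample_bilinear(img, UpsampleSpec(4))
        for r in range(3):
            for c in range(3):
                # block center (4r+1.5, 4c+1.5) straddles 4 equal-weight pixels
                block = out[4 * r + 1 : 4 * r + 3, 4 * c + 1 : 4 * c + 3]
                assert block.mean() == pytest.approx(img[r, c], abs=0.3)
        # exact at true sample points for odd factors
        out3 = bs.upsample_bilinear(img, UpsampleSpec(3))
        np.testing.assert_allclose(out3[1::3, 1::3], img, atol=1e-12)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            UpsampleSpec(0)


class TestCentroidMapping:
    def test_identity_at_factor_one(self):
        np.testing.assert_array_equal(bs.map_centroid_up((3.0, 4.0), 1), (3.0, 4.0))

    def test_origin_maps_to_block_center(self):
        np.testing.assert_array_equal(bs.map_centroid_up((0.0, 0.0), 4), (1.5, 1.5))

    def test_linearity_preserves_distances(self):
        a = bs.map_centroid_up(np.array([2.0, 5.0]), 4)
        b = bs.map_centroid_up(np.array([3.0, 5.0]), 4)
        assert np.hypot(*(b - a)) == pytest.approx(4.0)

    @given(
        st.floats(0, 30, allow_nan=False),
        st.floats(0, 30, allow_nan=False),
        st.integers(1, 8),
    )
    @settings(deadline=None, max_examples=50)
    def test_round_trip(self, r, c, factor):
        from beadspot.preprocess import map_centroid_down

        up = bs.map_centroid_up(np.array([r, c]), factor)
        np.testing.assert_allclose(map_centroid_down(up, factor), [r, c], atol=1e-9)


class TestSeedMask:
    def test_empty_centroids_give_empty_mask(self):
        mask = bs.render_seed_mask(np.empty((0, 2)), (16, 16))
        assert mask.data.sum() == 0

    def test_seed_block_placement(self):
        mask = bs.render_seed_mask(np.array([[1.5, 1.5]]), (8, 8))
        expected = {(1, 1), (1, 2), (2, 1), (2, 2)}
        assert set(map(tuple, np.argwhere(mask.data))) == expected

    def test_integer_original_centroid_rule(self):
        # original centroid (r, c) at factor 4 -> rows {4r+1, 4r+2}
        up = bs.map_centroid_up(np.array([[2.0, 3.0]]), 4)
        mask = bs.render_seed_mask(up, (32, 32))
        rows, cols = np.nonzero(mask.data)
        assert set(rows) == {9, 10} and set(cols) == {13, 14}

    def test_adjacent_beads_leave_two_px_gap(self):
        up = bs.map_centroid_up(np.array([[2.0, 2.0], [2.0, 3.0]]), 4)
        mask = bs.render_seed_mask(up, (32, 32))
        labeled = bs.label_components(mask.data)
        assert labeled.max() == 2
        cols = np.nonzero(mask.data.any(axis=0))[0]
        assert set(cols) == {9, 10, 13, 14}  # gap at columns 11-12

    def test_outside_centroids_skipped_with_count(self):
        mask = bs.render_seed_mask(np.array([[50.0, 50.0], [2.0, 2.0]]), (16, 16))
        assert mask.n_skipped == 1
        assert mask.data.sum() == 4

    @given(
        st.integers(0, 20),
        st.integers(0, 20),
        st.integers(0, 20),
        st.integers(0, 20),
    )
    @settings(deadline=None, max_examples=60)
    def test_separation_property(self, r1, c1, r2, c2):
        """Beads >= 1 original px apart keep 8-disjoint undilated seeds."""
        if np.hypot(r1 - r2, c1 - c2) < 1 and (r1, c1) != (r2, c2):
            return
        if (r1, c1) == (r2, c2):
            return
        up = bs.map_centroid_up(np.array([[r1, c1], [r2, c2]], float), 4)
        mask = bs.render_seed_mask(up, (96, 96))
        assert bs.label_components(mask.data).max() == 2


class TestCrossDilation:
    def test_zero_mask_unchanged(self):
        out = bs.dilate_seeds_cross(np.zeros((8, 8), dtype=np.uint8))
        assert out.data.sum() == 0 and out.dilated

    def test_single_seed_becomes_12_pixel_plus(self):
        mask = bs.render_seed_mask(np.array([[4.5, 4.5]]), (12, 12))
        out = bs.dilate_seeds_cross(mask)
        assert out.data.sum() == 12
        expected = {(3, 4), (3, 5), (4, 3), (4, 4), (4, 5), (4, 6),
                    (5, 3), (5, 4), (5, 5), (5, 6), (6, 4), (6, 5)}
        assert set(map(tuple, np.argwhere(out.data))) == expected

    def test_dilation_can_merge_adjacent_bead_seeds(self):
        # seeds of beads 1 original px apart become 4-adjacent after dilation
        up = bs.map_centroid_up(np.array([[2.0, 2.0], [2.0, 3.0]]), 4)
        mask = bs.render_seed_mask(up, (32, 32))
        assert bs.label_components(mask.data).max() == 2
        dil = bs.dilate_seeds_cross(mask)
        assert bs.label_components(dil.data).max() == 1

    @given(st.integers(0, 2**16 - 1))
    @settings(deadline=None, max_examples=30)
    def test_dilation_monotone(self, bits):
        mask = np.array([(bits >> i) & 1 for i in range(16)], dtype=np.uint8).reshape(4, 4)
        out = bs.dilate_seeds_cross(mask)
        assert (out.data >= mask).all()


def test_factor_rule_from_diameter_range():
    assert factor_for_diameter_range((2.0, 4.0)) == 4
    assert factor_for_diameter_range((8.0, 16.0)) == 1
    assert factor_for_diameter_range((1.0, 2.0)) == 8
    with pytest.raises(ValueError):
        factor_for_diameter_range((0.0, 4.0))
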