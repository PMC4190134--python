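"""Morphological toolbox: operator contracts against brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage

from endoseg import morpho
from oracles import (
    brute_distance_map,
    brute_max_filter,
    brute_min_filter,
    brute_reconstruction_by_dilation,
    brute_regional_maxima,
)


def rand_img(seed, shape=(24, 24), levels=32):
    return np.random.default_rng(seed).integers(0, levels, size=shape).astype(float)


class TestStructuringElements:
    def test_disk_is_euclidean_ball(self):
        fp = morpho.disk_footprint(2)
        expected = np.array(
            [
                [0, 0, 1, 0, 0],
                [0, 1, 1, 1, 0],
                [1, 1, 1, 1, 1],
                [0, 1, 1, 1, 0],
                [0, 0, 1, 0, 0],
            ],
            dtype=bool,
        )
        assert np.array_equal(fp, expected)

    def test_disk_radius_zero_is_single_pixel(self):
        assert np.array_equal(morpho.disk_footprint(0), np.ones((1, 1), bool))

    @pytest.mark.parametrize("angle,expected_shape", [(0.0, (1, 5)), (90.0, (5, 1))])
    def test_axis_aligned_segments(self, angle, expected_shape):
        fp = morpho.segment_footprint(5, angle)
        assert fp.shape == expected_shape
        assert fp.all()

    def test_segment_pixel_count_is_about_length(self):
        for angle in (0, 22.5, 45, 67.5, 90, 135):
            fp = morpho.segment_footprint(7, angle)
            assert 5 <= fp.sum() <= 9

    def test_invalid_elements_rejected(self):
        with pytest.raises(ValueError):
            morpho.StructuringElement("disk", radius=-1)
        with pytest.raises(ValueError):
            morpho.StructuringElement("segment", length=0)
        with pytest.raises(ValueError):
            morpho.StructuringElement("segment", length=3, orientation=180.0)


class TestAlternateSequentialFilter:
    def test_order_zero_is_identity(self):
        img = rand_img(0)
        assert np.array_equal(morpho.alternate_sequential_filter(img, 0), img)

    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 7.0)
        for order in (1, 2, 3):
            assert np.array_equal(
                morpho.alternate_sequential_filter(img, order), img
            )

    def test_isolated_bright_pixel_removed_at_order_one(self):
        img = np.zeros((15, 15))
        img[7, 7] = 10.0
        filtered = morpho.alternate_sequential_filter(img, 1)
        # oracle: closing leaves the spike, the opening removes it
        fp = morpho.disk_footprint(1)
        closed = brute_min_filter(brute_max_filter(img, fp), fp)
        expected = brute_max_filter(brute_min_filter(closed, fp), fp)
        assert np.array_equal(filtered, expected)
        assert filtered[7, 7] == 0.0

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            morpho.alternate_sequential_filter(np.zeros((4, 4)), -1)

    def test_filter_is_increasing(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            a = rng.integers(0, 30, size=(20, 20)).astype(float)
            b = a + rng.integers(0, 10, size=(20, 20))
            fa = morpho.alternate_sequential_filter(a, 2)
            fb = morpho.alternate_sequential_filter(b, 2)
            assert (fa <= fb + 1e-12).all()


class TestOpeningClosingOrder:
    def test_opening_below_identity_below_closing(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            img = rng.integers(0, 64, size=(20, 20)).astype(float)
            fp = morpho.disk_footprint(rng.integers(1, 3))
            assert (morpho.opening(img, fp) <= img).all()
            assert (img <= morpho.closing(img, fp)).all()


class TestHMaxima:
    def test_prominence_selects_peaks(self):
        # two peaks of heights 10 and 3 above a flat plateau; h=5 keeps one
        img = np.zeros((20, 20))
        img[5, 5] = 10.0
        img[14, 14] = 3.0
        markers = morpho.h_maxima_markers(img, 5.0)
        rec = brute_reconstruction_by_dilation(img - 5.0, img)
        expected = brute_regional_maxima(rec)
        assert np.array_equal(markers, expected)
        assert markers[5, 5] and not markers[14, 14]

    def test_h_zero_gives_regional_maxima(self):
        img = rand_img(3, shape=(16, 16))
        assert np.array_equal(
            morpho.h_maxima_markers(img, 0.0), brute_regional_maxima(img)
        )

    def test_single_plateau_maximum_yields_one_marker(self):
        img = np.zeros((20, 20))
        img[8:12, 8:12] = 6.0  # plateau of prominence 6
        markers = morpho.h_maxima_markers(img, 4.0)
        _, n = ndimage.label(markers, structure=np.ones((3, 3), int))
        assert n == 1
        rec = brute_reconstruction_by_dilation(img - 4.0, img)
        assert np.array_equal(markers, brute_regional_maxima(rec))

    def test_negative_h_rejected(self):
        with pytest.raises(ValueError):
            morpho.h_maxima_markers(np.zeros((4, 4)), -1.0)


class TestTopHat:
    def test_constant_image_zero(self):
        img = np.full((12, 12), 5.0)
        for dark in (True, False):
            assert np.array_equal(morpho.top_hat(img, 2, dark), np.zeros_like(img))

    def test_dark_line_extracted(self):
        img = np.full((15, 15), 100.0)
        img[7, :] = 20.0  # 1-px dark line
        fp = morpho.disk_footprint(2)
        expected = brute_min_filter(brute_max_filter(img, fp), fp) - img
        got = morpho.top_hat(img, 2, dark=True)
        assert np.array_equal(got, expected)
        assert (got[7, :] == 80.0).all()

    def test_nonnegative(self):
        img = rand_img(7)
        assert (morpho.top_hat(img, 2, dark=True) >= 0).all()
        assert (morpho.top_hat(img, 2, dark=False) >= 0).all()


class TestDistanceMap:
    def test_zero_on_set_one_next_to_it(self):
        b = np.zeros((9, 9), bool)
        b[4, 4] = True
        d = morpho.distance_map(b)
        assert d[4, 4] == 0.0
        assert d[4, 5] == 1.0
        assert d[5, 5] == pytest.approx(np.sqrt(2.0))

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(17)
        for _ in range(3):
            b = rng.random((32, 32)) < 0.04
            b[tuple(rng.integers(0, 32, 2))] = True
            assert np.allclose(morpho.distance_map(b), brute_distance_map(b))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            morpho.distance_map(np.zeros((8, 8), bool))


class TestWatershed:
    def test_single_marker_single_region(self):
        relief = rand_img(2, shape=(16, 16))
        markers = np.zeros((16, 16), bool)
        markers[8, 8] = True
        labels, lines = morpho.watershed_lines(relief, markers)
        assert labels.max() == 1
        assert (labels == 1).all()
        assert not lines.any()

    def test_two_point_markers_split_at_equidistant_column(self):
        relief = np.zeros((11, 15))
        markers = np.zeros((11, 15), bool)
        markers[5, 3] = markers[5, 11] = True
        labels, _ = morpho.watershed_lines(relief, markers)
        # brute-force nearest-marker assignment away from the midline
        assert (labels[:, :7] == labels[5, 3]).all()
        assert (labels[:, 8:] == labels[5, 11]).all()

    def test_label_count_equals_marker_components(self):
        rng = np.random.default_rng(23)
        relief = rng.random((32, 32))
        markers = np.zeros((32, 32), bool)
        for r, c in [(4, 4), (20, 9), (9, 25), (26, 26)]:
            markers[r, c] = True
        labels, _ = morpho.watershed_lines(relief, markers)
        assert labels.max() == 4
        assert set(np.unique(labels)) == {1, 2, 3, 4}

    def test_partition_property(self):
        rng = np.random.default_rng(29)
        relief = rng.random((24, 24))
        markers = rng.random((24, 24)) < 0.02
        markers[0, 0] = True
        labels, _ = morpho.watershed_lines(relief, markers)
        assert (labels > 0).all()  # regions fill the domain

    def test_empty_markers_rejected(self):
        with pytest.raises(ValueError):
            morpho.watershed_lines(np.zeros((8, 8)), np.zeros((8, 8), bool))


class TestSupOpenSegments:
    def test_long_bright_line_preserved(self):
        img = np.zeros((15, 15))
        img[7, 2:13] = 50.0
        out = morpho.sup_open_segments(img, 7)
        assert (out[7, 4:11] == 50.0).all()

    def test_isolated_pixel_removed(self):
        img = np.zeros((15, 15))
        img[7, 7] = 50.0
        out = morpho.sup_open_segments(img, 3)
        # oracle: the opening at each orientation removes the spike
        fp0 = morpho.segment_footprint(3, 0.0)
        expected0 = brute_max_filter(brute_min_filter(img, fp0), fp0)
        assert expected0[7, 7] == 0.0
        assert out[7, 7] == 0.0

    def test_anti_extensive(self):
        img = rand_img(31)
        assert (morpho.sup_open_segments(img, 5) <= img).all()


class TestPruneNonlinearSkeleton:
    def test_straight_line_unchanged(self):
        b = np.zeros((15, 21), bool)
        b[7, 2:19] = True
        assert np.array_equal(morpho.prune_nonlinear_skeleton(b, 7), b)

    def test_small_blob_removed(self):
        b = np.zeros((15, 15), bool)
        b[6:10, 6:10] = True  # diameter 4 < t_s
        assert not morpho.prune_nonlinear_skeleton(b, 7).any()

    def test_l_shape_keeps_both_arms(self):
        b = np.zeros((20, 20), bool)
        b[3:17, 3] = True
        b[16, 3:17] = True
        out = morpho.prune_nonlinear_skeleton(b, 7)
        assert out[5:13, 3].all()  # vertical arm away from corner
        assert out[16, 7:15].all()  # horizontal arm away from corner


class TestLabelsToContours:
    def test_boundary_between_two_halves(self):
        labels = np.ones((8, 8), int)
        labels[:, 4:] = 2
        contours = morpho.labels_to_contours(labels)
        assert contours[:, 3].all()
        assert contours.sum() == 8
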