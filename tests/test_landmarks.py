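"""Mask post-processing and landmark geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from slovasc import landmarks as lm
from slovasc import synthetic_data as sd


def _components(mask):
    _, n = ndimage.label(mask, structure=np.ones((3, 3)))
    return n


class TestBinarize:
    def test_boundary_value_included(self):
        assert lm.binarize(np.full((4, 4), 0.5)).all()

    def test_zero_map_is_empty(self):
        assert not lm.binarize(np.zeros((4, 4))).any()

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_matches_elementwise_oracle(self, seed):
        prob = np.random.default_rng(seed).random((16, 16))
        got = lm.binarize(prob)
        expect = np.array([[p >= 0.5 for p in row] for row in prob])
        assert np.array_equal(got, expect)


class TestCleanMask:
    def test_small_blob_removed(self):
        m = np.zeros((20, 20), bool)
        m[3, 3:8] = True  # 5-pixel blob
        assert not lm.clean_mask(m, 10).any()

    def test_boundary_sized_blob_kept(self):
        m = np.zeros((20, 20), bool)
        m[3, 3:13] = True  # exactly 10 pixels
        assert lm.clean_mask(m, 10).sum() == 10

    def test_salt_noise_removed_exactly(self, rng):
        vessel, _ = __import__("conftest").straight_vessel(5.0, length=200.0)
        noisy = vessel.copy()
        # sprinkle isolated specks away from the vessel (vessel occupies rows ~38-43)
        for _ in range(40):
            r = int(rng.integers(55, vessel.shape[0] - 2))
            c = int(rng.integers(2, vessel.shape[1] - 2))
            noisy[r, c] = True
        cleaned = lm.clean_mask(noisy, 10)
        assert np.array_equal(cleaned, vessel)

    def test_idempotent(self, rng):
        m = rng.random((64, 64)) > 0.7
        once = lm.clean_mask(m, 10)
        assert np.array_equal(lm.clean_mask(once, 10), once)


class TestBridgeGaps:
    def test_two_px_gap_in_straight_vessel_joined(self):
        m = np.zeros((20, 60), bool)
        m[9:12, 5:30] = True
        m[9:12, 32:55] = True  # 2-px gap at cols 30-31
        assert _components(m) == 2
        assert _components(lm.bridge_gaps(m, 3)) == 1

    def test_perpendicular_endpoints_not_joined(self):
        m = np.zeros((40, 40), bool)
        m[20, 5:18] = True        # horizontal, endpoint at (20, 17)
        m[23:36, 20] = True       # vertical, endpoint at (23, 20)
        out = lm.bridge_gaps(m, 5)
        assert _components(out) == 2

    def test_component_count_never_increases(self, rng):
        for _ in range(30):
            m = ndimage.binary_dilation(rng.random((48, 48)) > 0.92)
            out = lm.bridge_gaps(m, 3)
            assert _components(out) <= _components(m)

    def test_idempotent_on_synthetic_vessels(self):
        m = np.zeros((20, 60), bool)
        m[9:12, 5:30] = True
        m[9:12, 32:55] = True
        once = lm.bridge_gaps(m, 3)
        assert np.array_equal(lm.bridge_gaps(once, 3), once)

    def test_output_stays_within_dilated_support(self, rng):
        for _ in range(20):
            m = ndimage.binary_dilation(rng.random((48, 48)) > 0.9)
            out = lm.postprocess(m.astype(float), min_area_px=0, max_gap_px=3)
            allowed = ndimage.distance_transform_edt(~m) <= 3
            assert not (out & ~allowed).any()


class TestFoveaCentroid:
    def test_symmetric_block_centroid(self):
        m = np.zeros((40, 40), bool)
        m[10:13, 20:23] = True
        fp = lm.fovea_centroid(m)
        assert (fp.x_px, fp.y_px) == (21.0, 11.0)

    def test_empty_mask_absent(self):
        assert not lm.fovea_centroid(np.zeros((8, 8), bool)).present

    def test_disc_of_radius_60_centroid_matches_center(self):
        yy, xx = np.mgrid[0:300, 0:300]
        m = (yy - 140) ** 2 + (xx - 170) ** 2 <= 60**2
        fp = lm.fovea_centroid(m)
        assert abs(fp.x_px - 170) < 0.5 and abs(fp.y_px - 140) < 0.5


class TestFitDisc:
    def test_circle_radius_50(self):
        yy, xx = np.mgrid[0:200, 0:200]
        m = (yy - 100) ** 2 + (xx - 100) ** 2 <= 50**2
        od = lm.fit_disc(m)
        assert od.present
        assert od.diameter_D_px == pytest.approx(100, abs=1)
        assert od.axis_major_px == pytest.approx(od.axis_minor_px, abs=1)

    def test_axis_aligned_ellipse_120_by_80(self):
        yy, xx = np.mgrid[0:300, 0:300]
        m = ((yy - 150) / 40.0) ** 2 + ((xx - 150) / 60.0) ** 2 <= 1.0
        od = lm.fit_disc(m)
        assert od.diameter_D_px == pytest.approx((120 + 80) / 2, abs=1)
        assert od.axis_major_px == pytest.approx(120, abs=1)

    def test_empty_mask_absent(self):
        assert not lm.fit_disc(np.zeros((10, 10), bool)).present

    def test_rotation_equivariance_quarter_turn(self):
        yy, xx = np.mgrid[0:300, 0:300]
        m = ((yy - 120) / 40.0) ** 2 + ((xx - 170) / 60.0) ** 2 <= 1.0
        od = lm.fit_disc(m)
        od_rot = lm.fit_disc(np.rot90(m))
        assert od_rot.diameter_D_px == pytest.approx(od.diameter_D_px, abs=1)
        # rot90 maps (row, col) -> (n_cols - 1 - col, row)
        assert od_rot.center_y_px == pytest.approx(300 - 1 - od.center_x_px, abs=0.5)
        assert od_rot.center_x_px == pytest.approx(od.center_y_px, abs=0.5)

    def test_largest_component_used(self):
        yy, xx = np.mgrid[0:200, 0:200]
        m = (yy - 100) ** 2 + (xx - 100) ** 2 <= 40**2
        m[5:8, 5:8] = True  # small distractor blob
        od = lm.fit_disc(m)
        assert od.center_x_px == pytest.approx(100, abs=1)


class TestInferLateralityLocation:
    def _fovea(self, x, y):
        return lm.FoveaPoint(x_px=x, y_px=y, present=True)

    def _disc(self, x, y):
        return lm.OpticDisc(center_x_px=x, center_y_px=y, diameter_D_px=100,
                            axis_major_px=100, axis_minor_px=100, present=True)

    def test_central_fovea_disc_at_left_edge_is_left_macula(self):
        lat, loc = lm.infer_laterality_location(
            self._fovea(384, 384), self._disc(30, 384), (768, 768))
        assert (lat, loc) == ("left", "macula")

    def test_central_disc_without_fovea_is_disc_centered(self):
        lat, loc = lm.infer_laterality_location(
            lm.FoveaPoint(), self._disc(400, 384), (768, 768))
        assert loc == "disc"
        assert lat == "right"  # disc in the right half

    def test_no_landmarks_is_unknown(self):
        lat, loc = lm.infer_laterality_location(lm.FoveaPoint(), lm.OpticDisc(), (768, 768))
        assert (lat, loc) == ("unknown", "unknown")

    def test_synthetic_right_disc_scene_recovered(self, disc_scene):
        img, truth = disc_scene
        fovea = lm.fovea_centroid(np.zeros(img.pixels.shape, bool))
        disc = lm.fit_disc(truth.label_mask.disc)
        lat, loc = lm.infer_laterality_location(fovea, disc, img.pixels.shape)
        assert (lat, loc) == ("right", "disc")

    def test_synthetic_macula_scene_recovered(self, macula_scene):
        img, truth = macula_scene
        fovea = lm.fovea_centroid(truth.fovea_mask)
        disc = lm.fit_disc(truth.label_mask.disc)
        lat, loc = lm.infer_laterality_location(fovea, disc, img.pixels.shape)
        assert (lat, loc) == ("right", "macula")
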