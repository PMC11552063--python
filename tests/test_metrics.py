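"""Vascular measurement suite: skeletons, segments, every metric."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from slovasc import metrics as mx
from slovasc import synthetic_data as sd
from slovasc import zones
from slovasc.errors import ParameterError
from slovasc.landmarks import fit_disc

from conftest import straight_vessel


def knudtson_oracle(widths, k):
    """Hand-iterated pairing, written independently of the implementation."""
    vals = sorted(widths, reverse=True)
    while len(vals) > 1:
        nxt = []
        while len(vals) > 1:
            big = vals.pop(0)
            small = vals.pop(-1)
            nxt.append(k * (big**2 + small**2) ** 0.5)
        nxt.extend(vals)  # odd leftover carried
        vals = sorted(nxt, reverse=True)
    return vals[0]


class TestSkeleton:
    def test_wide_bar_skeleton_is_single_centerline(self):
        mask, _ = straight_vessel(5.0, length=200.0)
        skel = mx.skeletonize(mask)
        rows = np.nonzero(skel)[0]
        assert len(np.unique(rows)) <= 2  # essentially one row
        assert abs(skel.sum() - 200) < 15

    def test_empty_mask_empty_skeleton(self):
        assert not mx.skeletonize(np.zeros((10, 10), bool)).any()

    def test_component_count_preserved(self, rng):
        eight = np.ones((3, 3))
        for _ in range(100):
            m = ndimage.binary_dilation(rng.random((48, 48)) > 0.95, iterations=2)
            _, n_in = ndimage.label(m, structure=eight)
            _, n_out = ndimage.label(mx.skeletonize(m), structure=eight)
            assert n_in == n_out


class TestSegments:
    def test_plain_line_is_one_segment(self):
        mask, _ = straight_vessel(3.0, length=120.0)
        segs = mx.decompose_segments(mx.skeletonize(mask))
        assert len(segs) == 1
        assert segs[0].arc_length_px == pytest.approx(120, abs=8)
        assert segs[0].arc_length_px >= segs[0].chord_length_px - 1e-9

    def test_symmetric_y_gives_three_arms(self):
        shape = (160, 160)
        arms = [
            [(80.0, 80.0), (30.0, 80.0)],
            [(80.0, 80.0), (120.0, 40.0)],
            [(80.0, 80.0), (120.0, 120.0)],
        ]
        m = np.zeros(shape, bool)
        for verts in arms:
            c = sd.VesselCurve(kind="polyline", width_px=3, vessel_class="vein",
                               vertices=verts)
            m |= sd.render_vessel(c, 3, shape)
        segs = mx.decompose_segments(mx.skeletonize(m), min_segment_len=10)
        assert len(segs) == 3
        for seg in segs:
            assert seg.arc_length_px == pytest.approx(52, abs=12)

    def test_x_crossing_gives_four_segments(self):
        shape = (160, 160)
        m = np.zeros(shape, bool)
        for verts in ([(30.0, 30.0), (130.0, 130.0)], [(130.0, 30.0), (30.0, 130.0)]):
            c = sd.VesselCurve(kind="polyline", width_px=3, vessel_class="vein",
                               vertices=verts)
            m |= sd.render_vessel(c, 3, shape)
        segs = mx.decompose_segments(mx.skeletonize(m), min_segment_len=10)
        assert len(segs) == 4

    def test_diagonal_steps_count_sqrt2(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [2, 3]])
        seg = mx.VesselSegment(points=pts)
        assert seg.arc_length_px == pytest.approx(2 * np.sqrt(2) + 1)
        assert seg.chord_length_px == pytest.approx(np.hypot(2, 3))

    def test_short_paths_discarded(self):
        mask, _ = straight_vessel(3.0, length=6.0)
        assert mx.decompose_segments(mx.skeletonize(mask), min_segment_len=10) == []


class TestDensityAndFractal:
    def test_full_and_empty_density(self):
        roi = zones.whole_image_roi((20, 20))
        assert mx.vessel_density(np.ones((20, 20), bool), roi) == 1.0
        assert mx.vessel_density(np.zeros((20, 20), bool), roi) == 0.0

    def test_scene_density_equals_truth_ratio(self, macula_scene):
        _, truth = macula_scene
        roi = zones.whole_image_roi(truth.vessel_mask.shape)
        got = mx.vessel_density(truth.vessel_mask, roi)
        assert got == truth.vessel_mask.sum() / truth.vessel_mask.size

    def test_filled_square_fd_near_two(self):
        fd = mx.fractal_dimension(np.ones((512, 512), bool))
        assert 1.9 <= fd <= 2.0

    def test_line_fd_near_one(self):
        m = np.zeros((512, 512), bool)
        m[256, :] = True
        assert 0.9 <= mx.fractal_dimension(m) <= 1.1

    def test_empty_mask_fd_is_none(self):
        assert mx.fractal_dimension(np.zeros((64, 64), bool)) is None

    def test_tiny_array_without_enough_scales_is_none(self):
        assert mx.fractal_dimension(np.ones((8, 8), bool)) is None


class TestCaliber:
    def test_global_caliber_of_bar(self):
        mask, _ = straight_vessel(5.0, length=600.0)
        skel = mx.skeletonize(mask)
        assert mx.global_caliber(mask, skel) == pytest.approx(5.0, abs=0.5)

    def test_skeleton_only_mask_gives_one(self):
        mask, _ = straight_vessel(1.0, length=100.0)
        skel = mx.skeletonize(mask)
        assert mx.global_caliber(skel, skel) == 1.0

    def test_micron_conversion_is_multiplicative(self):
        mask, _ = straight_vessel(5.0, length=600.0)
        skel = mx.skeletonize(mask)
        px = mx.global_caliber(mask, skel)
        um = mx.global_caliber(mask, skel, scale_um_per_px=11.71)
        assert um == pytest.approx(px * 11.71)

    @pytest.mark.parametrize("width", [3.0, 7.0, 10.0, 15.0])
    def test_local_caliber_recovers_drawn_width(self, width):
        mask, _ = straight_vessel(width, length=400.0)
        segs = mx.decompose_segments(mx.skeletonize(mask))
        mx.attach_widths(segs, mask)
        assert mx.local_caliber(segs) == pytest.approx(width, abs=0.5)

    def test_equal_length_segments_average_plainly(self):
        s1 = mx.VesselSegment(points=np.column_stack([np.zeros(50, int), np.arange(50)]),
                              widths_px=np.full(50, 4.0))
        s2 = mx.VesselSegment(points=np.column_stack([np.full(50, 5, int), np.arange(50)]),
                              widths_px=np.full(50, 8.0))
        assert mx.local_caliber([s1, s2]) == pytest.approx(6.0)

    def test_length_weighted_mean(self):
        s1 = mx.VesselSegment(points=np.column_stack([np.zeros(91, int), np.arange(91)]),
                              widths_px=np.full(91, 4.0))  # arc 90
        s2 = mx.VesselSegment(points=np.column_stack([np.full(11, 5, int), np.arange(11)]),
                              widths_px=np.full(11, 8.0))  # arc 10
        assert mx.local_caliber([s1, s2]) == pytest.approx((90 * 4 + 10 * 8) / 100)
        assert mx.local_caliber([s1, s2], aggregation="mean") == pytest.approx(6.0)


class TestTortuosity:
    def test_straight_segment_is_zero(self):
        mask, _ = straight_vessel(5.0, length=400.0)
        seg = mx.decompose_segments(mx.skeletonize(mask))[0]
        assert mx.tortuosity_density(seg) == pytest.approx(0.0, abs=1e-6)

    def test_sinusoid_amplitude_ladder_is_strictly_increasing(self):
        values = []
        for a in (6.0, 10.0, 14.0, 18.0, 22.0):
            c = sd.VesselCurve(kind="sinusoid", width_px=5, vessel_class="vein",
                               start=(60.0, 20.0), angle=0.0, length=512.0,
                               amplitude=a, period=128.0, phase=np.pi / 2)
            m = sd.render_vessel(c, 5, (140, 560))
            segs = mx.decompose_segments(mx.skeletonize(m))
            assert len(segs) == 1
            values.append(mx.tortuosity_density(segs[0]))
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_semicircle_matches_single_arc_excess_over_length(self):
        r = 80.0
        c = sd.VesselCurve(kind="arc", width_px=5, vessel_class="vein",
                           center=(150.0, 150.0), radius=r, theta0=0.0, theta1=np.pi)
        m = sd.render_vessel(c, 5, (300, 300))
        seg = mx.decompose_segments(mx.skeletonize(m))[0]
        # n = 1 case of the Grisan measure: (arc/chord - 1) / arc length,
        # with arc/chord = pi/2 for a semicircle
        expect = (np.pi / 2 - 1.0) / (np.pi * r)
        assert mx.tortuosity_density(seg) == pytest.approx(expect, rel=0.10)


class TestKnudtson:
    def test_six_equal_widths_match_hand_iterated_oracle(self):
        got = mx.knudtson_equivalent([100.0] * 6, "artery")
        assert got == pytest.approx(knudtson_oracle([100.0] * 6, 0.88), rel=1e-12)
        assert got == pytest.approx(174.84, abs=0.01)

    def test_two_equal_vein_widths_closed_form(self):
        w = 70.0
        assert mx.knudtson_equivalent([w, w], "vein") == pytest.approx(0.95 * w * np.sqrt(2))

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariance_and_homogeneity(self, seed):
        r = np.random.default_rng(seed)
        widths = r.uniform(2.0, 20.0, size=int(r.integers(2, 9)))
        base = mx.knudtson_equivalent(widths, "vein")
        assert mx.knudtson_equivalent(r.permutation(widths), "vein") == pytest.approx(base)
        c = float(r.uniform(0.1, 10.0))
        assert mx.knudtson_equivalent(c * widths, "vein") == pytest.approx(c * base)

    def test_matches_oracle_on_random_sets(self, rng):
        for _ in range(25):
            widths = rng.uniform(3.0, 25.0, size=6)
            for cls, k in (("artery", 0.88), ("vein", 0.95)):
                assert mx.knudtson_equivalent(widths, cls) == pytest.approx(
                    knudtson_oracle(widths, k)
                )

    def test_fewer_than_two_is_none(self):
        assert mx.knudtson_equivalent([5.0], "artery") is None
        assert mx.knudtson_equivalent([], "vein") is None

    def test_odd_count_trimmed_to_largest_even(self):
        got = mx.knudtson_equivalent([10.0, 8.0, 6.0], "vein")
        assert got == pytest.approx(knudtson_oracle([10.0, 8.0], 0.95))

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ParameterError):
            mx.knudtson_equivalent([5.0, -1.0], "artery")


class TestAVR:
    def test_simple_ratios(self):
        assert mx.avr(150.0, 200.0) == 0.75
        assert mx.avr(123.4, 123.4) == 1.0
        assert mx.avr(None, 200.0) is None

    def test_artery_width_scaling_propagates_through_pairing(self):
        veins = [10.0, 9.0, 11.0, 10.5, 9.5, 10.2]
        arteries = [0.8 * w for w in veins]
        got = mx.avr(
            mx.knudtson_equivalent(arteries, "artery"),
            mx.knudtson_equivalent(veins, "vein"),
        )
        expect = 0.8 * knudtson_oracle(veins, 0.88) / knudtson_oracle(veins, 0.95)
        assert got == pytest.approx(expect)


class TestComputeAll:
    def test_macula_scene_yields_three_whole_image_records(self, macula_scene):
        img, truth = macula_scene
        rois = zones.rois_for_location("macula", fit_disc(truth.label_mask.disc),
                                       truth.vessel_mask.shape)
        recs = mx.compute_all(
            {"all": truth.vessel_mask, "artery": truth.artery_mask,
             "vein": truth.vein_mask},
            rois, image_id="m")
        assert len(recs) == 3
        assert {r.roi for r in recs} == {"whole"}
        assert {r.vessel_class for r in recs} == {"all", "artery", "vein"}

    def test_disc_scene_yields_nine_records_with_null_globals_in_zones(self, disc_scene):
        img, truth = disc_scene
        rois = zones.rois_for_location("disc", fit_disc(truth.label_mask.disc),
                                       truth.vessel_mask.shape)
        recs = mx.compute_all(
            {"all": truth.vessel_mask, "artery": truth.artery_mask,
             "vein": truth.vein_mask},
            rois, image_id="d")
        assert len(recs) == 9
        for rec in recs:
            if rec.roi in ("zoneB", "zoneC"):
                assert rec.vessel_density is None
                assert rec.fractal_dimension is None
                assert rec.global_caliber is None
            else:
                assert rec.vessel_density is not None
            if rec.vessel_class == "all" and rec.CRAE is None:
                assert rec.CRVE is None  # equivalents live on their class rows

    def test_records_compose_from_module_level_metrics(self, disc_scene):
        img, truth = disc_scene
        roi = zones.whole_image_roi(truth.vessel_mask.shape)
        recs = mx.compute_all(
            {"all": truth.vessel_mask, "artery": truth.artery_mask,
             "vein": truth.vein_mask},
            [roi], image_id="d")
        artery = next(r for r in recs if r.vessel_class == "artery")
        assert artery.vessel_density == mx.vessel_density(truth.artery_mask, roi)
        skel = mx.skeletonize(truth.artery_mask)
        assert artery.global_caliber == mx.global_caliber(truth.artery_mask, skel)
        assert artery.fractal_dimension == mx.fractal_dimension(truth.artery_mask, roi)
        segs = mx.decompose_segments(skel)
        mx.attach_widths(segs, truth.artery_mask)
        assert artery.local_caliber == pytest.approx(mx.local_caliber(segs))
        assert artery.CRAE == pytest.approx(
            mx.knudtson_equivalent([s.mean_width_px for s in segs], "artery")
        )

    def test_avr_consistency_on_all_rows(self, disc_scene):
        img, truth = disc_scene
        roi = zones.whole_image_roi(truth.vessel_mask.shape)
        recs = mx.compute_all(
            {"all": truth.vessel_mask, "artery": truth.artery_mask,
             "vein": truth.vein_mask},
            [roi], image_id="d")
        by_cls = {r.vessel_class: r for r in recs}
        assert by_cls["all"].AVR == pytest.approx(
            by_cls["artery"].CRAE / by_cls["vein"].CRVE
        )

    def test_micron_units_flagged_and_scaled(self, macula_scene):
        img, truth = macula_scene
        roi = zones.whole_image_roi(truth.vessel_mask.shape)
        masks = {"all": truth.vessel_mask, "artery": truth.artery_mask,
                 "vein": truth.vein_mask}
        px = mx.compute_all(masks, [roi], image_id="m")
        um = mx.compute_all(masks, [roi], scale_um_per_px=11.71875, image_id="m")
        assert px[0].units == "px" and um[0].units == "um"
        assert um[0].local_caliber == pytest.approx(px[0].local_caliber * 11.71875)
        assert um[0].vessel_density == px[0].vessel_density  # dimensionless
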