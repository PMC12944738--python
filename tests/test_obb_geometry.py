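"""OBB parsing, axis geometry, end classification, tracking and calibration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lpkin import (
    OBBDetection,
    axis_midpoints,
    build_end_tracks,
    calibrate,
    classify_ends,
    read_obb_detections,
)
from lpkin.errors import InsufficientDataError, ParseError, ValidationError


def _box(frame, corners, label="bar"):
    return OBBDetection(frame, label, np.asarray(corners, dtype=float))


def rect_corners(center, length, width, angle):
    """Corners of an oriented rectangle, consecutive order, P1->P2 = long side."""
    c, s = np.cos(angle), np.sin(angle)
    axis = np.array([c, s])
    normal = np.array([-s, c])
    half_l, half_w = length / 2.0, width / 2.0
    center = np.asarray(center, dtype=float)
    return np.array([
        center - half_l * axis + half_w * normal,
        center + half_l * axis + half_w * normal,
        center + half_l * axis - half_w * normal,
        center - half_l * axis - half_w * normal,
    ])


# ---------------------------------------------------------------------------
# parsing

class TestReadDetections:
    def test_yolo_line_denormalizes_to_pixels(self, tmp_path):
        (tmp_path / "frame_0.txt").write_text(
            "0 0.1 0.1 0.2 0.1 0.2 0.15 0.1 0.15\n")
        dets = read_obb_detections(tmp_path, "yolo_obb_txt", image_size=(1000, 1000))
        assert len(dets) == 1
        np.testing.assert_allclose(
            dets[0].corners,
            [(100, 100), (200, 100), (200, 150), (100, 150)])
        assert dets[0].class_label == "bar"
        assert dets[0].confidence is None

    def test_empty_directory_gives_empty_list(self, tmp_path):
        assert read_obb_detections(tmp_path, "yolo_obb_txt",
                                   image_size=(100, 100)) == []

    def test_wrong_coordinate_count_is_a_parse_error(self, tmp_path):
        (tmp_path / "frame_3.txt").write_text("0 0.1 0.1 0.2 0.1 0.2 0.15 0.1\n")
        with pytest.raises(ParseError, match="frame_3.txt:1"):
            read_obb_detections(tmp_path, "yolo_obb_txt", image_size=(100, 100))

    def test_coordinates_outside_unit_interval_rejected(self, tmp_path):
        (tmp_path / "f1.txt").write_text("0 0.1 0.1 1.2 0.1 1.2 0.2 0.1 0.2\n")
        with pytest.raises(ParseError, match="outside"):
            read_obb_detections(tmp_path, "yolo_obb_txt", image_size=(100, 100))

    def test_long_csv_roundtrip(self, tmp_path):
        path = tmp_path / "dets.csv"
        path.write_text(
            "frame,class,x1,y1,x2,y2,x3,y3,x4,y4,conf\n"
            "0,bar,0,0,10,0,10,2,0,2,0.9\n"
            "1,0,0,0,10,0,10,2,0,2,0.8\n")
        dets = read_obb_detections(path, "long_csv")
        assert [d.frame_index for d in dets] == [0, 1]
        assert all(d.class_label == "bar" for d in dets)
        assert dets[0].confidence == pytest.approx(0.9)

    def test_missing_csv_columns_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("frame,class,x1\n0,bar,1\n")
        with pytest.raises(ParseError, match="missing columns"):
            read_obb_detections(path, "long_csv")


class TestDetectionValidation:
    def test_zero_area_box_rejected(self):
        with pytest.raises(ValidationError, match="zero-area"):
            _box(0, [(0, 0), (1, 1), (2, 2), (3, 3)])

    def test_bowtie_corner_order_repaired(self):
        # P3/P4 swapped relative to consecutive order
        crossed = [(0, 0), (10, 0), (0, 2), (10, 2)]
        box = _box(0, crossed)
        ends = axis_midpoints(box)
        assert np.linalg.norm(ends.M1 - ends.M2) == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# axis midpoints and end classification

class TestAxisMidpoints:
    @pytest.mark.parametrize(
        "corners, L1, L2, M1, M2",
        [
            # long side first: principal axis midpoints on the short sides
            ([(0, 0), (10, 0), (10, 2), (0, 2)], 10, 2, (0, 1), (10, 1)),
            # short side first: other branch
            ([(0, 0), (2, 0), (2, 10), (0, 10)], 2, 10, (1, 0), (1, 10)),
            # exact tie takes the second branch
            ([(0, 0), (4, 0), (4, 4), (0, 4)], 4, 4, (2, 0), (2, 4)),
        ],
    )
    def test_examples(self, corners, L1, L2, M1, M2):
        ends = axis_midpoints(_box(0, corners))
        assert ends.L1 == pytest.approx(L1)
        assert ends.L2 == pytest.approx(L2)
        np.testing.assert_allclose(ends.M1, M1)
        np.testing.assert_allclose(ends.M2, M2)

    @given(
        cx=st.floats(-1000, 1000), cy=st.floats(-1000, 1000),
        length=st.floats(10, 500), width=st.floats(1, 9),
        angle=st.floats(0, 2 * np.pi),
    )
    def test_midpoint_separation_equals_longer_side(self, cx, cy, length,
                                                    width, angle):
        corners = rect_corners((cx, cy), length, width, angle)
        ends = axis_midpoints(_box(0, corners))
        sep = np.linalg.norm(ends.M1 - ends.M2)
        assert sep == pytest.approx(length, rel=1e-9)

    @given(
        # horizontal bars (endpoint-y tie) are excluded: there the tie-break
        # legitimately depends on corner order
        angle=st.floats(0.05, np.pi - 0.05),
        shift=st.integers(0, 3),
    )
    def test_classification_invariant_to_cyclic_corner_rotation(self, angle, shift):
        corners = rect_corners((300, 400), 200, 20, angle)
        base = classify_ends(axis_midpoints(_box(0, corners)))
        rolled = classify_ends(axis_midpoints(_box(0, np.roll(corners, shift, axis=0))))
        np.testing.assert_allclose(base[0], rolled[0], atol=1e-9)
        np.testing.assert_allclose(base[1], rolled[1], atol=1e-9)


class TestClassifyEnds:
    @pytest.mark.parametrize(
        "m1, m2, expect_moving",
        [
            ((512, 120), (300, 600), (512, 120)),  # smaller y is higher on screen
            ((0, 400), (900, 50), (900, 50)),
            ((0, 100), (50, 100), (50, 100)),      # exact tie: second endpoint
        ],
    )
    def test_height_rule(self, m1, m2, expect_moving):
        from lpkin.obb_geometry import AxisEndpoints
        moving, fixed = classify_ends(AxisEndpoints(
            M1=np.asarray(m1, dtype=float), M2=np.asarray(m2, dtype=float),
            L1=1.0, L2=1.0))
        np.testing.assert_allclose(moving, expect_moving)


# ---------------------------------------------------------------------------
# track building and calibration

def _bar_detection(frame, moving, fixed=(100.0, 900.0), width=20.0):
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    axis = (moving - fixed) / np.linalg.norm(moving - fixed)
    normal = np.array([-axis[1], axis[0]])
    return _box(frame, [fixed + width * normal, moving + width * normal,
                        moving - width * normal, fixed - width * normal])


class TestBuildEndTracks:
    def test_contiguous_frames_have_no_gap_flags(self):
        dets = [_bar_detection(i, (600, 400 - 10 * i)) for i in range(3)]
        (track,) = build_end_tracks(dets, fps=50, image_height=1080)
        assert not track.gap_mask.any()
        assert list(track.frame_indices) == [0, 1, 2]

    def test_single_frame_gap_linearly_interpolated_and_flagged(self):
        dets = [_bar_detection(0, (600, 400)), _bar_detection(2, (620, 380))]
        (track,) = build_end_tracks(dets, fps=50, image_height=1080, max_gap=2)
        assert list(track.frame_indices) == [0, 1, 2]
        assert list(track.gap_mask) == [False, True, False]
        np.testing.assert_allclose(track.moving_px[1], [610, 390], atol=1e-9)

    def test_long_gap_splits_into_unusably_short_blocks(self):
        dets = [_bar_detection(0, (600, 400)), _bar_detection(10, (620, 380))]
        with pytest.raises(InsufficientDataError):
            build_end_tracks(dets, fps=50, image_height=1080, max_gap=3)

    def test_long_gap_between_usable_blocks_yields_two_tracks(self):
        dets = ([_bar_detection(i, (600, 400 - i)) for i in range(5)]
                + [_bar_detection(i, (600, 300 - i)) for i in range(50, 55)])
        tracks = build_end_tracks(dets, fps=50, image_height=1080, max_gap=3)
        assert [len(t) for t in tracks] == [5, 5]

    def test_marker_pair_uses_box_centers(self):
        dets = [
            _box(0, rect_corners((600, 200), 30, 20, 0.1), "moving_marker"),
            _box(0, rect_corners((100, 900), 30, 20, 0.1), "fixed_marker"),
            _box(1, rect_corners((610, 190), 30, 20, 0.1), "moving_marker"),
            _box(1, rect_corners((100, 900), 30, 20, 0.1), "fixed_marker"),
        ]
        (track,) = build_end_tracks(dets, fps=50, image_height=1080)
        np.testing.assert_allclose(track.moving_px[0], [600, 200], atol=1e-9)
        np.testing.assert_allclose(track.fixed_px[0], [100, 900], atol=1e-9)

    def test_swapped_marker_labels_corrected_by_height_rule(self, caplog):
        dets = [
            _box(i, rect_corners((600, 900), 30, 20, 0.0), "moving_marker")
            for i in range(2)
        ] + [
            _box(i, rect_corners((100, 200), 30, 20, 0.0), "fixed_marker")
            for i in range(2)
        ]
        with caplog.at_level("WARNING", logger="lpkin.obb_geometry"):
            (track,) = build_end_tracks(dets, fps=50, image_height=1080)
        assert "height rule" in caplog.text
        # the higher-in-image (smaller y) point wins the moving slot
        np.testing.assert_allclose(track.moving_px[0], [100, 200], atol=1e-9)


class TestCalibrate:
    def test_scale_from_constant_pixel_length(self):
        # 1100 px apart every frame, real bar 2.20 m -> 0.002 m/px
        dets = [_bar_detection(i, (100 + 1100 * np.cos(0.8 - 0.01 * i),
                                   900 - 1100 * np.sin(0.8 - 0.01 * i)))
                for i in range(10)]
        (track,) = build_end_tracks(dets, fps=50, image_height=1080)
        traj = calibrate(track, 2.20)
        assert traj.scale_s == pytest.approx(0.002, rel=1e-9)
        assert traj.scale_s * traj.L_pixel_mean == pytest.approx(2.20, abs=1e-9)

    def test_mean_metre_bar_length_equals_real_length(self, rng):
        # jittered pixel lengths: the calibration identity still holds exactly
        dets = []
        for i in range(20):
            r = 1000 + rng.normal(0, 5)
            ang = 0.7 + 0.01 * i
            dets.append(_bar_detection(
                i, (100 + r * np.cos(ang), 900 - r * np.sin(ang))))
        (track,) = build_end_tracks(dets, fps=50, image_height=1080)
        traj = calibrate(track, 2.20)
        fixed_px_med = np.median(track.fixed_px, axis=0)
        # re-measure in metre space using per-frame fixed ends
        fixed_m = np.column_stack([
            traj.scale_s * (track.fixed_px[:, 0] - fixed_px_med[0]),
            traj.scale_s * (fixed_px_med[1] - track.fixed_px[:, 1]),
        ])
        lengths_m = np.linalg.norm(traj.moving_m - fixed_m, axis=1)
        assert lengths_m.mean() == pytest.approx(2.20, abs=1e-12)

    def test_noiseless_synthetic_scale_recovered(self, noiseless_press):
        out = noiseless_press
        (track,) = build_end_tracks(out.detections, fps=out.config.fps,
                                    image_height=out.config.image_size[1])
        traj = calibrate(track, out.config.L_real)
        assert traj.scale_s == pytest.approx(out.true_scale, abs=1e-6)

    def test_noiseless_roundtrip_recovers_trajectory(self, noiseless_press):
        out = noiseless_press
        cfg = out.config
        (track,) = build_end_tracks(out.detections, fps=cfg.fps,
                                    image_height=cfg.image_size[1])
        traj = calibrate(track, cfg.L_real)
        theta = out.truth["theta"].to_numpy()
        expected = cfg.L_real * np.column_stack([np.cos(theta), np.sin(theta)])
        assert np.max(np.linalg.norm(traj.moving_m - expected, axis=1)) < 1e-6
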