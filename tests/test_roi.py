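import numpy as np
import pytest

from rppgnet import roi
from rppgnet.roi import (
    DegenerateRoiError,
    LandmarkFormatError,
    LandmarkSet,
    RoiBox,
    build_clips,
    cheek_box,
    crop_resize_stitch,
    forehead_box,
    parse_landmarks,
    write_landmarks,
)
from rppgnet.synthetic import landmark_template


def _landmarks_with(overrides: dict[int, tuple[float, float]], frame_index=0) -> LandmarkSet:
    pts = landmark_template((128, 128)).copy()
    for i, (x, y) in overrides.items():
        pts[i] = (x, y)
    return LandmarkSet(points=pts, frame_index=frame_index)


class TestLandmarkIO:
    def test_round_trip_preserves_rows_and_coordinates(self, rng, tmp_path):
        sets = [LandmarkSet(points=rng.uniform(0, 100, (68, 2)), frame_index=i) for i in range(3)]
        path = tmp_path / "lms.csv"
        write_landmarks(sets, path)
        parsed = parse_landmarks(path)
        assert len(parsed) == 3
        for a, b in zip(sets, parsed):
            assert a.frame_index == b.frame_index
            np.testing.assert_array_equal(a.points, b.points)

    def test_wrong_column_count_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        cols = ["frame"] + [f"x_{i}" for i in range(67)] + [f"y_{i}" for i in range(68)]
        path.write_text(",".join(cols) + "\n" + ",".join(["0"] * len(cols)) + "\n")
        with pytest.raises(LandmarkFormatError, match="columns"):
            parse_landmarks(path)

    def test_malformed_row_names_the_row(self, rng, tmp_path):
        path = tmp_path / "bad_row.csv"
        write_landmarks([LandmarkSet(points=rng.uniform(0, 99, (68, 2)), frame_index=i)
                         for i in range(3)], path)
        lines = path.read_text().splitlines()
        parts = lines[2].split(",")
        parts[5] = "oops"
        lines[2] = ",".join(parts)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(LandmarkFormatError, match="row 1"):
            parse_landmarks(path)

    def test_wrong_point_count_rejected(self):
        with pytest.raises(LandmarkFormatError):
            LandmarkSet(points=np.zeros((67, 2)), frame_index=0)


class TestBoxGeometry:
    def test_cheek_box_hand_example(self):
        lms = _landmarks_with({
            3: (100, 200), 13: (220, 205),
            40: (120, 180), 41: (130, 182), 46: (170, 181), 47: (180, 183),
            50: (150, 260), 52: (170, 258),
        })
        box = cheek_box(lms)
        assert (box.x_left, box.y_top, box.width, box.height) == (100, 183, 120, 75)

    def test_forehead_box_hand_example(self):
        lms = _landmarks_with({19: (120, 170), 24: (200, 168)})
        cheek = RoiBox(100, 183, 120, 75)
        box = forehead_box(lms, cheek)
        assert (box.x_left, box.y_top, box.width, box.height) == (120, 130.5, 80, 37.5)

    def test_forehead_equal_brow_heights(self):
        lms = _landmarks_with({19: (120, 170), 24: (200, 170)})
        box = forehead_box(lms, RoiBox(100, 183, 120, 75))
        assert box.y_top == 170 - 0.5 * 75

    @pytest.mark.parametrize("overrides", [
        # zero height: upper lip at eyelid level
        {40: (0, 180), 41: (0, 180), 46: (0, 180), 47: (0, 180), 50: (10, 180), 52: (20, 180)},
        # zero width: jaw points coincide horizontally
        {3: (100, 200), 13: (100, 205)},
    ])
    def test_degenerate_cheek_raises(self, overrides):
        with pytest.raises(DegenerateRoiError):
            cheek_box(_landmarks_with(overrides))

    def test_degenerate_forehead_zero_width(self):
        lms = _landmarks_with({19: (150, 170), 24: (150, 168)})
        with pytest.raises(DegenerateRoiError):
            forehead_box(lms, RoiBox(100, 183, 120, 75))

    def test_boxes_translation_equivariant(self, rng):
        pts = landmark_template((128, 128))
        lms = LandmarkSet(points=pts, frame_index=0)
        dx, dy = 7.0, -3.0
        shifted = LandmarkSet(points=pts + (dx, dy), frame_index=0)
        cb, cbs = cheek_box(lms), cheek_box(shifted)
        assert (cbs.x_left, cbs.y_top) == (cb.x_left + dx, cb.y_top + dy)
        assert (cbs.width, cbs.height) == (cb.width, cb.height)
        fb, fbs = forehead_box(lms, cb), forehead_box(shifted, cbs)
        assert (fbs.x_left, fbs.y_top) == (fb.x_left + dx, fb.y_top + dy)


class TestStitching:
    def test_uniform_frame_stays_uniform(self):
        frame = np.full((100, 120, 3), 77, dtype=np.uint8)
        out = crop_resize_stitch(frame, RoiBox(10, 40, 60, 30), RoiBox(20, 10, 40, 15))
        assert out.shape == (96, 96, 3)
        assert np.all(out == 77)

    def test_output_shape_for_random_boxes(self, rng):
        frame = rng.integers(0, 255, (80, 90, 3), dtype=np.uint8)
        for _ in range(10):
            cb = RoiBox(rng.uniform(0, 30), rng.uniform(20, 40), rng.uniform(10, 50), rng.uniform(10, 30))
            fb = RoiBox(rng.uniform(0, 30), rng.uniform(2, 10), rng.uniform(10, 50), rng.uniform(5, 10))
            assert crop_resize_stitch(frame, cb, fb).shape == (96, 96, 3)

    def test_cheek_on_top_forehead_below(self):
        frame = np.zeros((100, 100, 3), dtype=np.uint8)
        frame[50:80, 10:90] = (255, 0, 0)  # cheek region painted red
        frame[5:25, 20:80] = (0, 0, 255)   # forehead region painted blue
        out = crop_resize_stitch(frame, RoiBox(10, 50, 80, 30), RoiBox(20, 5, 60, 20))
        assert np.all(out[:64] == (255, 0, 0))
        assert np.all(out[64:] == (0, 0, 255))

    def test_stitched_pixels_translation_invariant(self, rng):
        base = rng.integers(0, 255, (60, 70, 3), dtype=np.uint8)
        frame = np.zeros((100, 110, 3), dtype=np.uint8)
        frame[10:70, 15:85] = base
        shifted = np.zeros((100, 110, 3), dtype=np.uint8)
        shifted[14:74, 20:90] = base
        cb, fb = RoiBox(20, 40, 40, 20), RoiBox(25, 15, 30, 12)
        cb2, fb2 = RoiBox(25, 44, 40, 20), RoiBox(30, 19, 30, 12)
        np.testing.assert_array_equal(
            crop_resize_stitch(frame, cb, fb), crop_resize_stitch(shifted, cb2, fb2)
        )

    def test_box_outside_frame_raises(self):
        frame = np.zeros((50, 50, 3), dtype=np.uint8)
        with pytest.raises(DegenerateRoiError):
            crop_resize_stitch(frame, RoiBox(100, 100, 20, 20), RoiBox(10, 10, 10, 9))

    def test_forehead_above_frame_clipped_with_warning(self):
        frame = np.full((50, 60, 3), 33, dtype=np.uint8)
        with pytest.warns(UserWarning, match="clipped"):
            out = crop_resize_stitch(frame, RoiBox(5, 20, 40, 20), RoiBox(10, -8, 30, 12))
        assert out.shape == (96, 96, 3)


class TestBuildClips:
    def test_example_counts_and_starts(self):
        frames = np.zeros((160, 4, 4, 3), dtype=np.uint8)
        clips = build_clips(frames, clip_len=128, stride=8)
        assert [c.start_frame for c in clips] == [0, 8, 16, 24, 32]

    @pytest.mark.parametrize("n,clip_len,stride", [
        (128, 128, 8), (129, 128, 8), (135, 128, 8), (136, 128, 8),
        (200, 64, 16), (64, 64, 1), (301, 100, 7),
    ])
    def test_count_matches_closed_form(self, n, clip_len, stride):
        frames = np.zeros((n, 2, 2, 3), dtype=np.uint8)
        clips = build_clips(frames, clip_len=clip_len, stride=stride)
        assert len(clips) == (n - clip_len) // stride + 1
        assert all(len(c) == clip_len for c in clips)

    def test_short_input_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert build_clips(np.zeros((127, 2, 2, 3)), clip_len=128, stride=8) == []
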