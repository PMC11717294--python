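"""Grip feature geometry, gap filling and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chopgrip.datatypes import (
    ChopstickPose,
    GripSequence,
    HandLandmarkFrame,
    TrialProtocol,
)
from chopgrip.errors import FeatureFailure, GeometryError, SequenceError
from chopgrip.features import (
    compute_frame_features,
    extract_features,
    feature_matrix,
    fill_gaps,
    normalize_features,
    point_segment_distance,
)
from chopgrip.simulate import generate_grip_sequence


class TestPointSegmentDistance:
    @pytest.mark.parametrize(
        "point, segment, expected",
        [
            ((0.5, 0.0), [(0, 0), (1, 0)], 0.0),  # on the line
            ((0.0, 1.0), [(0, 0), (1, 0)], 1.0),
            ((3.0, 4.0), [(0, 0), (0, 2)], 3.0),  # |ax+by+c|/sqrt(a^2+b^2), x=0
            ((5.0, 0.0), [(0, 0), (1, 0)], 0.0),  # beyond the segment: line, not clip
        ],
    )
    def test_known_distances(self, point, segment, expected):
        assert point_segment_distance(np.array(point), np.array(segment)) == pytest.approx(
            expected
        )

    def test_degenerate_segment_rejected(self):
        with pytest.raises(GeometryError):
            point_segment_distance(np.array([1.0, 1.0]), np.array([[2, 2], [2, 2]]))

    def test_vertical_mode_measures_image_y_offset(self):
        seg = np.array([[0.0, 0.0], [2.0, 2.0]])  # slope 1
        assert point_segment_distance(np.array([1.0, 4.0]), seg, "vertical") == pytest.approx(3.0)
        with pytest.raises(GeometryError):
            point_segment_distance(np.array([1.0, 0.0]), np.array([[0, 0], [0, 2]]), "vertical")


def frame_from(points, t=0.0):
    return HandLandmarkFrame(t=t, points=np.asarray(points, dtype=float))


def straight_pose(y_upper=0.0, y_lower=10.0):
    return ChopstickPose(
        np.array([[0.0, y_upper], [100.0, y_upper]]),
        np.array([[0.0, y_lower], [100.0, y_lower]]),
    )


class TestComputeFrameFeatures:
    def test_fingertip_on_chopstick_line_gives_zero_a(self):
        pts = np.zeros((21, 2))
        pts[8] = (50.0, 0.0)  # fingertip II on the upper line
        out = compute_frame_features(frame_from(pts), straight_pose())
        assert out.a == 0.0

    def test_coincident_fingertips_give_zero_d(self):
        pts = np.zeros((21, 2))
        pts[12] = pts[16] = (30.0, 40.0)
        out = compute_frame_features(frame_from(pts), straight_pose())
        assert out.d == 0.0

    def test_matches_simulator_analytic_truth(self, four_finger_sequence):
        """Per-frame a, b, c, d equal the simulator's independently computed
        analytic distances to 1e-9."""
        seq = four_finger_sequence
        truth = seq.meta["truth_abcd"]
        for i in range(0, len(seq), 37):
            out = compute_frame_features(seq.landmark_frame(i), seq.pose(i))
            np.testing.assert_allclose(out.distances(), truth[i], atol=1e-9)

    def test_missing_pose_is_a_feature_failure(self):
        pose = ChopstickPose(None, None, source="missing")
        with pytest.raises(FeatureFailure):
            compute_frame_features(frame_from(np.zeros((21, 2))), pose)

    def test_invalid_required_landmark_is_a_feature_failure(self):
        pts = np.zeros((21, 2))
        pts[12] = np.nan  # fingertip III invalid
        with pytest.raises(FeatureFailure):
            compute_frame_features(frame_from(pts), straight_pose())


class TestFillGaps:
    def make_frames(self, n=5):
        seq = generate_grip_sequence(
            "palm", TrialProtocol(duration_s=1.0, noise_sd_px=0, dropout_rate=0), seed=1
        )
        return [
            compute_frame_features(seq.landmark_frame(i), seq.pose(i)) for i in range(n)
        ]

    def test_no_failures_is_identity(self):
        frames = self.make_frames()
        out = fill_gaps(list(frames))
        assert len(out) == len(frames)
        assert all(a is b for a, b in zip(out, frames))
        assert sum(f.filled for f in out) == 0

    def test_single_failure_copies_predecessor(self):
        frames = self.make_frames()
        gapped = frames[:2] + [None] + frames[3:]
        out = fill_gaps(gapped)
        assert len(out) == len(frames)
        assert out[2].filled
        assert out[2].a == frames[1].a and out[2].d == frames[1].d
        np.testing.assert_array_equal(out[2].landmark_xy, frames[1].landmark_xy)

    def test_leading_failures_trimmed(self):
        frames = self.make_frames()
        out = fill_gaps([None, None] + frames)
        assert len(out) == len(frames)
        assert not out[0].filled

    def test_run_longer_than_max_gap_dropped(self):
        frames = self.make_frames(8)
        gapped = frames[:2] + [None] * 3 + frames[5:]
        out = fill_gaps(gapped, max_gap=2)
        assert len(out) == 5  # the 3-frame gap is excluded entirely

    def test_all_failed_is_a_sequence_error(self):
        with pytest.raises(SequenceError):
            fill_gaps([None, None, None])


class TestNormalize:
    def test_none_mode_is_identity(self):
        frames = TestFillGaps().make_frames()
        assert normalize_features(frames, "none") is frames

    def test_hand_length_mode_is_scale_invariant(self, four_finger_sequence):
        seq = four_finger_sequence
        frames = [
            compute_frame_features(seq.landmark_frame(i), seq.pose(i)) for i in range(5)
        ]
        scaled = []
        for i in range(5):
            lm = HandLandmarkFrame(t=seq.t[i], points=seq.landmarks[i] * 2.0)
            pose = ChopstickPose(seq.upper[i] * 2.0, seq.lower[i] * 2.0)
            scaled.append(compute_frame_features(lm, pose))
        a = normalize_features(frames, "hand_length")
        b = normalize_features(scaled, "hand_length")
        for fa, fb in zip(a, b):
            np.testing.assert_allclose(fa.distances(), fb.distances(), atol=1e-9)
            np.testing.assert_allclose(fa.landmark_xy, fb.landmark_xy, atol=1e-9)

    def test_zero_hand_length_rejected(self):
        pts = np.zeros((21, 2))
        frame = compute_frame_features(frame_from(pts), straight_pose(y_upper=1.0))
        with pytest.raises(GeometryError):
            normalize_features([frame], "hand_length")


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    s=st.floats(0.1, 10.0),
    tx=st.floats(-200, 200),
    ty=st.floats(-200, 200),
    angle=st.floats(0, 2 * np.pi),
)
def test_distance_features_scale_translation_rotation_behaviour(s, tx, ty, angle):
    """a-d scale with a similarity transform's scale and ignore its rotation
    and translation."""
    rng = np.random.default_rng(99)
    pts = rng.uniform(0, 100, size=(21, 2))
    pose = straight_pose(y_upper=-5.0, y_lower=110.0)
    base = compute_frame_features(frame_from(pts), pose).distances()

    R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    T = lambda p: (p @ R.T) * s + (tx, ty)
    moved = compute_frame_features(
        frame_from(T(pts)),
        ChopstickPose(T(pose.upper), T(pose.lower)),
    ).distances()
    np.testing.assert_allclose(moved, base * s, rtol=1e-9, atol=1e-7)


def test_vectorized_feature_matrix_matches_frame_by_frame(four_finger_sequence):
    seq = four_finger_sequence
    cols = feature_matrix(seq)
    frames = extract_features(seq)
    assert len(cols["t"]) == len(frames)
    got = np.column_stack([cols["a"], cols["b"], cols["c"], cols["d"]])
    want = np.vstack([f.distances() for f in frames])
    np.testing.assert_allclose(got, want, atol=1e-12)


def test_fill_count_equals_dropout_count_within_max_gap():
    proto = TrialProtocol(duration_s=5.0, noise_sd_px=0.0, dropout_rate=0.1, seed=2)
    seq = generate_grip_sequence("three_finger", proto, seed=2)
    cols = feature_matrix(seq, max_gap=50)  # large gap: every dropout is filled
    n_missing = int((seq.sources == "missing").sum())
    leading = 0
    for s in seq.sources:
        if s != "missing":
            break
        leading += 1
    assert int(cols["filled"].sum()) == n_missing - leading
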