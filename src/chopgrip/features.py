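"""Per-frame grip features from hand landmarks and chopstick poses.

Four distances characterize the grip in each frame:

``a``
    fingertip of finger II (index) to the upper chopstick,
``b``
    first joint of finger III (middle, counted from the tip) to the upper
    chopstick,
``c``
    fingertip of finger III to the lower chopstick,
``d``
    fingertip of finger III to fingertip of finger IV (ring).

The chopstick distances are unsigned perpendicular distances to the
infinite supporting line of the fitted segment — invariant to camera roll
and to how much of the stick the tape covers.  An image-vertical variant
(plain |Δy| to the line's y at the point's x) is selectable for fidelity
experiments.  Frames whose pose is missing or whose required landmarks are
invalid are filled from the previous computed frame, mirroring the
previous-frame rule used for detection; runs of failures longer than
``max_gap`` stay missing and are excluded downstream.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    FINGERTIP_II,
    FINGERTIP_III,
    FINGERTIP_IV,
    FIRST_JOINT_III,
    ChopstickPose,
    GripFeatureFrame,
    GripSequence,
    HandLandmarkFrame,
)
from .errors import FeatureFailure, GeometryError, SequenceError

REQUIRED_LANDMARKS = (FINGERTIP_II, FIRST_JOINT_III, FINGERTIP_III, FINGERTIP_IV)

DEFAULT_MAX_GAP = 5


def point_segment_distance(
    point: np.ndarray, segment: np.ndarray, mode: str = "perpendicular"
) -> float:
    """Distance from a point to the infinite line through a segment.

    ``mode="perpendicular"`` (default) is the unsigned perpendicular
    distance; ``mode="vertical"`` is the unsigned image-y offset between the
    point and the line evaluated at the point's x (undefined for vertical
    lines).
    """
    p = np.asarray(point, dtype=float)
    seg = np.asarray(segment, dtype=float)
    a, b = seg[0], seg[1]
    d = b - a
    norm = float(np.hypot(*d))
    if norm == 0:
        raise GeometryError("degenerate (zero-length) segment")
    if mode == "perpendicular":
        return abs(d[0] * (p[1] - a[1]) - d[1] * (p[0] - a[0])) / norm
    if mode == "vertical":
        if d[0] == 0:
            raise GeometryError("vertical-distance mode undefined for a vertical line")
        y_on_line = a[1] + (p[0] - a[0]) * d[1] / d[0]
        return abs(p[1] - y_on_line)
    raise ValueError(f"unknown distance mode {mode!r}")


def compute_frame_features(
    landmarks: HandLandmarkFrame,
    pose: ChopstickPose,
    mode: str = "perpendicular",
) -> GripFeatureFrame:
    """Compute one frame's feature vector.

    Raises :class:`FeatureFailure` when the pose is missing or a required
    landmark is invalid; callers treat that as a gap to fill.
    """
    if pose.missing:
        raise FeatureFailure(f"frame {pose.frame_index}: chopstick pose missing")
    if not landmarks.valid[list(REQUIRED_LANDMARKS)].all():
        bad = [i for i in REQUIRED_LANDMARKS if not landmarks.valid[i]]
        raise FeatureFailure(f"invalid required landmarks {bad}")
    pts = landmarks.points
    a = point_segment_distance(pts[FINGERTIP_II], pose.upper, mode)
    b = point_segment_distance(pts[FIRST_JOINT_III], pose.upper, mode)
    c = point_segment_distance(pts[FINGERTIP_III], pose.lower, mode)
    d = float(np.hypot(*(pts[FINGERTIP_III] - pts[FINGERTIP_IV])))
    return GripFeatureFrame(
        t=landmarks.t,
        a=a,
        b=b,
        c=c,
        d=d,
        landmark_xy=pts.ravel().copy(),
        chopstick_xy=np.concatenate([pose.upper.ravel(), pose.lower.ravel()]),
        filled=False,
    )


def extract_features(
    sequence: GripSequence,
    mode: str = "perpendicular",
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[GripFeatureFrame]:
    """Per-frame features for a whole sequence, with gap filling.

    Frames whose pose is missing are filled from the previous computed
    frame (see :func:`fill_gaps`); leading failures are trimmed.
    """
    frames: list[GripFeatureFrame | None] = []
    for i in range(len(sequence)):
        try:
            frames.append(
                compute_frame_features(sequence.landmark_frame(i), sequence.pose(i), mode)
            )
        except FeatureFailure:
            frames.append(None)
    return fill_gaps(frames, max_gap=max_gap)


def fill_gaps(
    feature_frames: list, max_gap: int = DEFAULT_MAX_GAP
) -> list[GripFeatureFrame]:
    """Replace failed frames (None) by a flagged copy of their predecessor.

    Leading failures are trimmed.  Runs of failures longer than ``max_gap``
    are dropped entirely (carrying a stale frame indefinitely would
    fabricate data).  Raises :class:`SequenceError` when nothing survives.
    """
    start = 0
    while start < len(feature_frames) and feature_frames[start] is None:
        start += 1
    if start == len(feature_frames):
        raise SequenceError("every frame in the sequence failed")
    out: list[GripFeatureFrame] = []
    pending = 0
    last: GripFeatureFrame | None = None
    for frame in feature_frames[start:]:
        if frame is None:
            pending += 1
            continue
        if 0 < pending <= max_gap and last is not None:
            for _ in range(pending):
                out.append(
                    GripFeatureFrame(
                        t=last.t,
                        a=last.a,
                        b=last.b,
                        c=last.c,
                        d=last.d,
                        landmark_xy=last.landmark_xy.copy(),
                        chopstick_xy=last.chopstick_xy.copy(),
                        filled=True,
                    )
                )
        pending = 0
        out.append(frame)
        last = frame
    return out


def normalize_features(
    frames: list[GripFeatureFrame], mode: str = "none"
) -> list[GripFeatureFrame]:
    """Optionally rescale features by hand length.

    ``mode="none"`` returns the input unchanged.  ``mode="hand_length"``
    divides all distances, and all coordinates relative to the wrist, by the
    frame's wrist-to-fingertip-III distance, making features dimensionless
    and camera-distance invariant.
    """
    if mode == "none":
        return frames
    if mode != "hand_length":
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = []
    for fr in frames:
        pts = fr.landmark_xy.reshape(21, 2)
        wrist = pts[0]
        L = float(np.hypot(*(pts[FINGERTIP_III] - wrist)))
        if L == 0:
            raise GeometryError("zero hand length; cannot normalize")
        out.append(
            GripFeatureFrame(
                t=fr.t,
                a=fr.a / L,
                b=fr.b / L,
                c=fr.c / L,
                d=fr.d / L,
                landmark_xy=((pts - wrist) / L).ravel(),
                chopstick_xy=(
                    (fr.chopstick_xy.reshape(4, 2) - wrist) / L
                ).ravel(),
                filled=fr.filled,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Vectorized fast path used by the pipeline (same math as above)
# ---------------------------------------------------------------------------


def feature_matrix(sequence: GripSequence, max_gap: int = DEFAULT_MAX_GAP) -> dict:
    """Vectorized per-frame features for a sequence.

    Returns a dict of equal-length 1-D arrays: the four distances ``a``-
    ``d``, the 10 fingertip coordinate channels ``tip{I..V}_{x,y}``, and a
    boolean ``filled`` mask.  Missing-pose frames are filled from the
    previous frame exactly as in :func:`fill_gaps`.
    """
    from .datatypes import FINGERTIPS

    n = len(sequence)
    ok = np.array([str(s) != "missing" for s in sequence.sources])
    if not ok.any():
        raise SequenceError("every frame in the sequence failed")

    lm = sequence.landmarks
    up, lo = sequence.upper, sequence.lower

    def line_dist(p, seg):
        a, b = seg[:, 0], seg[:, 1]
        d = b - a
        norm = np.hypot(d[:, 0], d[:, 1])
        return np.abs(d[:, 0] * (p[:, 1] - a[:, 1]) - d[:, 1] * (p[:, 0] - a[:, 0])) / norm

    with np.errstate(invalid="ignore"):
        cols = {
            "a": line_dist(lm[:, FINGERTIP_II], up),
            "b": line_dist(lm[:, FIRST_JOINT_III], up),
            "c": line_dist(lm[:, FINGERTIP_III], lo),
            "d": np.hypot(*(lm[:, FINGERTIP_III] - lm[:, FINGERTIP_IV]).T),
        }
    for name, idx in FINGERTIPS.items():
        cols[f"tip{name}_x"] = lm[:, idx, 0].copy()
        cols[f"tip{name}_y"] = lm[:, idx, 1].copy()

    # previous-frame fill (indices of last good frame, capped at max_gap)
    idx = np.arange(n)
    last_good = np.where(ok, idx, -1)
    np.maximum.accumulate(last_good, out=last_good)
    age = idx - last_good
    keep = (last_good >= 0) & (age <= max_gap)
    if not keep.any():
        raise SequenceError("no usable frames after gap handling")
    src = last_good[keep]
    filled = ~ok[keep]
    return {
        **{k: v[src] for k, v in cols.items()},
        "filled": filled,
        "t": sequence.t[keep],
    }
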