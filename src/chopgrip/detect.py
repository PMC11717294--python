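"""Tape-color chopstick detection.

The chopsticks are wrapped in colored tape (upper: blue, lower: green) so
they can be located against the background by color alone: convert the
frame to HSV, threshold on hue/saturation/value, clean the mask with a
morphological opening, and fit a line segment as the principal axis of the
mask pixels.  When detection fails in a frame, the previous frame's
geometry is carried forward for up to ``max_gap`` frames before the pose is
declared missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import ChopstickPose
from .errors import ChopgripError, DetectionFailure

#: frames a lost chopstick may be carried forward before becoming missing
DEFAULT_MAX_GAP = 5


@dataclass(frozen=True)
class ColorSpec:
    """HSV window for one tape color.

    ``hue_range`` is in degrees on the [0, 360) hue wheel (may wrap, e.g.
    (330, 30) for red); ``saturation_min`` and ``value_min`` in [0, 1].
    """

    name: str
    hue_range: tuple[float, float]
    saturation_min: float = 0.4
    value_min: float = 0.3
    min_pixels: int = 30

    def __post_init__(self) -> None:
        lo, hi = self.hue_range
        if not (0 <= lo < 360 and 0 <= hi < 360):
            raise ValueError("hue_range must lie on the [0, 360) wheel")
        if self.min_pixels < 1:
            raise ValueError("min_pixels must be >= 1")


#: default tape mapping: upper chopstick blue, lower green (swappable)
DEFAULT_COLOR_SPECS = {
    "upper": ColorSpec("upper", hue_range=(200.0, 260.0)),
    "lower": ColorSpec("lower", hue_range=(80.0, 160.0)),
}


def segment_color(frame_image: np.ndarray, spec: ColorSpec) -> np.ndarray:
    """Binary mask of pixels inside the spec's HSV window.

    A one-pixel morphological opening suppresses speckle.  ``frame_image``
    must be an (H, W, 3) color image (uint8 or float in [0, 1]).
    """
    from skimage.color import rgb2hsv
    from skimage.morphology import footprint_rectangle, opening

    frame_image = np.asarray(frame_image)
    if frame_image.ndim != 3 or frame_image.shape[-1] != 3:
        raise ChopgripError(
            f"segment_color needs an (H, W, 3) color image, got shape {frame_image.shape}"
        )
    hsv = rgb2hsv(frame_image)
    hue = hsv[..., 0] * 360.0
    lo, hi = spec.hue_range
    in_hue = (hue >= lo) & (hue <= hi) if lo <= hi else (hue >= lo) | (hue <= hi)
    mask = in_hue & (hsv[..., 1] >= spec.saturation_min) & (hsv[..., 2] >= spec.value_min)
    return opening(mask, footprint_rectangle((3, 3)))


def _largest_component(mask: np.ndarray) -> np.ndarray:
    from skimage.measure import label

    lab = label(mask, connectivity=2)
    if lab.max() <= 1:
        return mask
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == counts.argmax()


def fit_line_segment(mask: np.ndarray, min_pixels: int = 1) -> np.ndarray:
    """Fit a line segment to a binary mask by principal-axis analysis.

    The axis is the first principal component of the mask pixel coordinate
    covariance; the endpoints are the extreme projections of mask pixels
    onto that axis.  Returns a (2, 2) array of (x, y) endpoints.

    Raises :class:`DetectionFailure` when the mask has fewer than
    ``min_pixels`` pixels (or fewer than 2, below which no axis exists);
    warns when the blob is nearly isotropic (axis ratio < 1.5), where the
    principal direction is unstable.
    """
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([cols, rows]).astype(float)  # (x, y)
    if len(pts) < max(min_pixels, 2):
        raise DetectionFailure(
            f"mask has {len(pts)} pixels, below the minimum of {max(min_pixels, 2)}"
        )
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    if evals[0] > 0 and np.sqrt(evals[-1] / evals[0]) < 1.5:
        warnings.warn(
            "nearly isotropic blob: fitted axis is low-confidence", stacklevel=2
        )
    proj = (pts - centroid) @ axis
    return np.stack([centroid + proj.min() * axis, centroid + proj.max() * axis])


def detect_chopstick(frame_image: np.ndarray, spec: ColorSpec) -> np.ndarray:
    """Segment one tape color and fit its line segment.

    When several blobs share the color, the largest connected component is
    kept.  Raises :class:`DetectionFailure` when no acceptable blob exists.
    """
    mask = segment_color(frame_image, spec)
    if mask.sum() < spec.min_pixels:
        raise DetectionFailure(
            f"{spec.name}: {int(mask.sum())} in-range pixels < min_pixels={spec.min_pixels}"
        )
    return fit_line_segment(_largest_component(mask), spec.min_pixels)


def detect_pose(
    frame_image: np.ndarray,
    prev: ChopstickPose | None = None,
    specs: dict[str, ColorSpec] | None = None,
    *,
    frame_index: int = 0,
    max_gap: int = DEFAULT_MAX_GAP,
    prev_age: int = 0,
) -> ChopstickPose:
    """Detect both chopsticks in one frame, with previous-frame fallback.

    When both tapes are found the pose has source ``"detected"``.  When
    either detection fails and a previous pose exists no more than
    ``max_gap`` frames old, the previous geometry is reused unchanged with
    source ``"carried_forward"``; otherwise the pose is ``"missing"``.
    ``prev_age`` counts frames since the last genuine detection.
    """
    specs = specs or DEFAULT_COLOR_SPECS
    if set(specs) != {"upper", "lower"}:
        raise ChopgripError("specs must contain exactly the 'upper' and 'lower' tapes")
    try:
        upper = detect_chopstick(frame_image, specs["upper"])
        lower = detect_chopstick(frame_image, specs["lower"])
        return ChopstickPose(upper, lower, source="detected", frame_index=frame_index)
    except DetectionFailure:
        if prev is not None and not prev.missing and prev_age < max_gap:
            return ChopstickPose(
                prev.upper, prev.lower, source="carried_forward", frame_index=frame_index
            )
        return ChopstickPose(None, None, source="missing", frame_index=frame_index)


def track_sequence(
    frames: np.ndarray,
    specs: dict[str, ColorSpec] | None = None,
    *,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[ChopstickPose]:
    """Run :func:`detect_pose` over an image stack, threading the previous pose.

    Returns one :class:`ChopstickPose` per frame.  The per-sequence
    detection rate is available via :func:`detection_rate`.
    """
    if len(frames) == 0:
        raise ChopgripError("track_sequence needs at least one frame")
    poses: list[ChopstickPose] = []
    prev: ChopstickPose | None = None
    age = 0
    for i, frame in enumerate(frames):
        pose = detect_pose(
            frame, prev, specs, frame_index=i, max_gap=max_gap, prev_age=age
        )
        if pose.source == "detected":
            prev, age = pose, 0
        elif pose.source == "carried_forward":
            age += 1
        poses.append(pose)
    return poses


def detection_rate(poses: list[ChopstickPose]) -> float:
    """Fraction of frames with a genuine (non-carried, non-missing) detection."""
    return sum(p.source == "detected" for p in poses) / len(poses)
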