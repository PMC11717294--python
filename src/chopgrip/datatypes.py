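"""Core domain types.

Coordinates are image pixels: origin at the top-left corner, x to the right,
y downward.  The hand skeleton follows the standard 21-landmark layout used
by single-camera hand pose estimators: wrist at index 0, then four joints
per digit in thumb-to-little order, with the fingertip last within each
digit.  Fingers are numbered with Roman numerals in the anatomical
convention: I = thumb, II = index, III = middle, IV = ring, V = little.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ProtocolError

# ---------------------------------------------------------------------------
# Landmark layout
# ---------------------------------------------------------------------------

WRIST = 0
#: landmark indices per finger, proximal to distal (fingertip last)
FINGER_INDICES: dict[str, tuple[int, int, int, int]] = {
    "I": (1, 2, 3, 4),
    "II": (5, 6, 7, 8),
    "III": (9, 10, 11, 12),
    "IV": (13, 14, 15, 16),
    "V": (17, 18, 19, 20),
}
FINGERTIPS: dict[str, int] = {f: idx[-1] for f, idx in FINGER_INDICES.items()}

#: landmarks entering the per-frame grip features
FINGERTIP_II = 8
FIRST_JOINT_III = 11  # first joint counted from the fingertip of finger III
FINGERTIP_III = 12
FINGERTIP_IV = 16

N_LANDMARKS = 21

POSE_SOURCES = ("detected", "carried_forward", "missing")


# ---------------------------------------------------------------------------
# Per-frame containers
# ---------------------------------------------------------------------------


@dataclass
class HandLandmarkFrame:
    """One frame's 21 hand landmarks.

    Parameters
    ----------
    t : float
        Timestamp in seconds.
    points : ndarray of shape (21, 2)
        Landmark pixel coordinates.
    valid : ndarray of shape (21,), bool
        Per-landmark validity flags.
    handedness : {"right", "left"}
    """

    t: float
    points: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]
    handedness: str = "right"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"expected ({N_LANDMARKS}, 2) landmark array, got {self.points.shape}"
            )
        if self.valid is None:
            self.valid = np.ones(N_LANDMARKS, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        finite = np.isfinite(self.points).all(axis=1)
        self.valid = self.valid & finite


@dataclass
class ChopstickPose:
    """Upper and lower chopstick line segments for one frame.

    ``upper`` and ``lower`` are (2, 2) arrays of segment endpoints, or None
    when ``source == "missing"``.  ``carried_forward`` poses reuse the last
    detected geometry unchanged.
    """

    upper: np.ndarray | None
    lower: np.ndarray | None
    source: str = "detected"
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.source not in POSE_SOURCES:
            raise ValueError(f"unknown pose source {self.source!r}")
        for name in ("upper", "lower"):
            seg = getattr(self, name)
            if seg is not None:
                seg = np.asarray(seg, dtype=float)
                if seg.shape != (2, 2):
                    raise ValueError(f"{name} segment must have shape (2, 2)")
                setattr(self, name, seg)
        if self.source != "missing":
            if self.upper is None or self.lower is None:
                raise ValueError("non-missing pose requires both segments")
            if not (np.isfinite(self.upper).all() and np.isfinite(self.lower).all()):
                raise ValueError("non-missing pose requires finite endpoints")

    @property
    def missing(self) -> bool:
        return self.source == "missing"


@dataclass
class GripFeatureFrame:
    """The per-frame grip feature vector.

    The four distances (pixels) are:

    a
        fingertip of finger II to the upper chopstick line,
    b
        first joint of finger III to the upper chopstick line,
    c
        fingertip of finger III to the lower chopstick line,
    d
        fingertip of finger III to fingertip of finger IV (Euclidean).

    ``landmark_xy`` carries the 42 landmark coordinates and ``chopstick_xy``
    the 8 chopstick endpoint coordinates.  ``filled`` marks frames whose
    values were substituted from the previous frame after a detection or
    feature failure.
    """

    t: float
    a: float
    b: float
    c: float
    d: float
    landmark_xy: np.ndarray
    chopstick_xy: np.ndarray
    filled: bool = False

    def distances(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d])


# ---------------------------------------------------------------------------
# Sequence container (array-backed for speed)
# ---------------------------------------------------------------------------


@dataclass
class GripSequence:
    """One trial: an ordered landmark + chopstick time series.

    Array-backed so that feature extraction and summarization vectorize over
    frames.  ``sources`` holds one of :data:`POSE_SOURCES` per frame; frames
    whose chopstick detection dropped out have non-finite chopstick rows and
    source ``"missing"`` until tracking carries geometry forward.
    """

    t: np.ndarray  # (n,)
    landmarks: np.ndarray  # (n, 21, 2)
    upper: np.ndarray  # (n, 2, 2)
    lower: np.ndarray  # (n, 2, 2)
    sources: np.ndarray  # (n,) of str
    label: str | None = None  # "traditional" / "nontraditional"
    archetype: str | None = None
    seed: int | None = None
    fps: float = 30.0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)

    def landmark_frame(self, i: int) -> HandLandmarkFrame:
        return HandLandmarkFrame(t=float(self.t[i]), points=self.landmarks[i])

    def pose(self, i: int) -> ChopstickPose:
        src = str(self.sources[i])
        if src == "missing":
            return ChopstickPose(None, None, source="missing", frame_index=i)
        return ChopstickPose(self.upper[i], self.lower[i], source=src, frame_index=i)

    def copy(self) -> "GripSequence":
        return GripSequence(
            t=self.t.copy(),
            landmarks=self.landmarks.copy(),
            upper=self.upper.copy(),
            lower=self.lower.copy(),
            sources=self.sources.copy(),
            label=self.label,
            archetype=self.archetype,
            seed=self.seed,
            fps=self.fps,
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# Simulation protocol and grip archetypes
# ---------------------------------------------------------------------------

FINGER_ORDER = ("I", "II", "III", "IV", "V")


@dataclass(frozen=True)
class TrialProtocol:
    """Recording protocol for one trial.

    Defaults encode the measurement protocol: a 10 s hold with the
    chopsticks opened and closed twice per second, filmed at 30 fps.
    """

    duration_s: float = 10.0
    open_close_hz: float = 2.0
    fps: float = 30.0
    noise_sd_px: float = 1.5
    dropout_rate: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ProtocolError("duration_s must be positive")
        if self.open_close_hz <= 0:
            raise ProtocolError("open_close_hz must be positive")
        if self.fps < 2 * self.open_close_hz:
            raise ProtocolError(
                f"fps ({self.fps}) must be at least twice the open/close "
                f"frequency ({self.open_close_hz} Hz) to satisfy Nyquist"
            )
        if not 0 <= self.dropout_rate < 1:
            raise ProtocolError("dropout_rate must lie in [0, 1)")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass(frozen=True)
class GripArchetype:
    """Kinematic template for one chopstick-holding style.

    ``amplitude_deg`` gives the peak flexion of each finger about its
    knuckle; ``phase`` the per-finger phase offset (radians); ``coupling``
    names the fingers whose motion drives the upper chopstick;
    ``lower_support`` says whether finger IV braces the lower chopstick,
    keeping it static.  ``hand_sway_px`` is a whole-hand translation
    amplitude used by the palm-driven styles.  ``contact_jitter_px``
    randomizes the chopstick-finger contact points per sequence (the
    "others" style: palm-like motion with atypical contact points).
    """

    name: str
    amplitude_deg: tuple[float, float, float, float, float]
    phase: tuple[float, float, float, float, float]
    coupling: tuple[str, ...]
    lower_support: bool
    hand_sway_px: float = 0.0
    contact_jitter_px: float = 0.0

    def __post_init__(self) -> None:
        for f in self.coupling:
            if f not in FINGER_ORDER:
                raise ValueError(f"unknown finger {f!r} in coupling")
        if self.name == "four_finger":
            if not self.lower_support:
                raise ValueError("four_finger requires lower_support")
            if not {"I", "II", "III"} <= set(self.coupling):
                raise ValueError("four_finger couples fingers I, II and III")

    @property
    def binary_label(self) -> str:
        return "traditional" if self.name == "four_finger" else "nontraditional"


#: Kinematic archetypes for the four grip categories.  Traditional
#: (four-finger) grip: fingers I-III drive the upper chopstick with large
#: excursions while finger IV braces the static lower chopstick, so the
#: III-IV fingertip distance oscillates strongly.  Three-finger: finger IV
#: is uncoupled but moves in sympathy with III, and nothing braces the
#: lower chopstick.  Palm: near-rigid fingers, the whole hand sways.
#: Others: palm-like motion with randomized chopstick contact points.
ARCHETYPES: dict[str, GripArchetype] = {
    "four_finger": GripArchetype(
        name="four_finger",
        amplitude_deg=(15.0, 22.0, 25.0, 3.0, 3.0),
        phase=(np.pi, 0.0, 0.0, 0.0, 0.0),
        coupling=("I", "II", "III"),
        lower_support=True,
    ),
    "three_finger": GripArchetype(
        name="three_finger",
        amplitude_deg=(12.0, 18.0, 20.0, 18.0, 6.0),
        phase=(np.pi, 0.0, 0.0, 0.0, 0.0),
        coupling=("I", "II", "III"),
        lower_support=False,
    ),
    "palm": GripArchetype(
        name="palm",
        amplitude_deg=(2.0, 2.0, 2.0, 2.0, 2.0),
        phase=(0.0, 0.0, 0.0, 0.0, 0.0),
        coupling=(),
        lower_support=False,
        hand_sway_px=8.0,
    ),
    "other": GripArchetype(
        name="other",
        amplitude_deg=(2.5, 2.5, 2.5, 2.5, 2.5),
        phase=(0.0, 0.0, 0.0, 0.0, 0.0),
        coupling=(),
        lower_support=False,
        hand_sway_px=7.0,
        contact_jitter_px=10.0,
    ),
}

GRIP_CLASSES = tuple(ARCHETYPES)  # 4-level taxonomy
NONTRADITIONAL_CLASSES = ("three_finger", "palm", "other")


# ---------------------------------------------------------------------------
# Survey types
# ---------------------------------------------------------------------------

DCDQ_N_ITEMS = 15
#: standard subscale split: items 1-6 control during movement, 7-10 fine
#: motor / handwriting, 11-15 general coordination
DCDQ_SUBSCALES: dict[str, tuple[int, ...]] = {
    "control_during_movement": (1, 2, 3, 4, 5, 6),
    "fine_motor_handwriting": (7, 8, 9, 10),
    "general_coordination": (11, 12, 13, 14, 15),
}


@dataclass
class DcdqScore:
    """Raw DCDQ subscale sums and total (each item rated 1-5)."""

    control_during_movement: float
    fine_motor_handwriting: float
    general_coordination: float
    total: float


@dataclass
class SurveyRecord:
    """One child's questionnaire row."""

    child_age: int  # 6 or 7
    sex: str  # "boy" / "girl"
    cohabitation: bool  # grandparent-grandchild cohabitation
    training: bool  # prior chopstick training
    dcdq_items: list  # 15 ints in 1..5, None where missing
    grip_class: str  # one of GRIP_CLASSES
    rater_labels: list | None = None
    maternal_age: float | None = None
    maternal_taught: bool | None = None
    maternal_knows: bool | None = None
    maternal_can_use: bool | None = None
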