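"""Synthetic hand-kinematics and survey-cohort generator.

Emulates the measurement protocol for a single trial — the child holds the
chopsticks in the dominant hand for 10 seconds, opening and closing them
twice per second — and produces labeled landmark + chopstick sequences for
the four grip archetypes, rasterized frames with color-taped chopsticks for
detection testing, and synthetic questionnaire tables drawn from a
multinomial-logit generative model with user-set log-odds.

The hand skeleton is a fixed 21-landmark base pose (digitized once from a
traced adult hand outline), scaled to a configurable hand length.  The
default hand length is 133.5 px at a nominal 1 px/mm, the cohort mean
dominant-hand length.  Finger motion is sinusoidal flexion about each
knuckle; the upper chopstick rotates about the thumb-index web with an
amplitude proportional to the coupled fingers' flexion; the lower chopstick
is static when finger IV braces it and wobbles otherwise.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    ARCHETYPES,
    FINGER_INDICES,
    FINGER_ORDER,
    GRIP_CLASSES,
    GripArchetype,
    GripSequence,
    TrialProtocol,
)
from .errors import ConfigurationError, RenderError

# ---------------------------------------------------------------------------
# Base hand pose (canonical units: hand length 1.0; x right, y down,
# fingers pointing up). Right hand, thumb on the -x side.
# ---------------------------------------------------------------------------

BASE_HAND = np.array(
    [
        [0.00, 0.00],  # 0 wrist
        [-0.25, -0.15],  # 1 thumb CMC
        [-0.38, -0.32],  # 2 thumb MCP
        [-0.46, -0.46],  # 3 thumb IP
        [-0.52, -0.58],  # 4 thumb tip
        [-0.20, -0.52],  # 5 index MCP
        [-0.24, -0.70],  # 6 index PIP
        [-0.26, -0.82],  # 7 index DIP
        [-0.28, -0.92],  # 8 index tip
        [-0.05, -0.55],  # 9 middle MCP
        [-0.06, -0.75],  # 10 middle PIP
        [-0.07, -0.89],  # 11 middle DIP
        [-0.07, -1.00],  # 12 middle tip
        [0.09, -0.53],  # 13 ring MCP
        [0.11, -0.72],  # 14 ring PIP
        [0.12, -0.84],  # 15 ring DIP
        [0.13, -0.94],  # 16 ring tip
        [0.22, -0.48],  # 17 little MCP
        [0.25, -0.62],  # 18 little PIP
        [0.27, -0.72],  # 19 little DIP
        [0.28, -0.80],  # 20 little tip
    ]
)

DEFAULT_HAND_LENGTH_PX = 133.5
DEFAULT_ORIGIN = (260.0, 320.0)

CHOPSTICK_LENGTH_PX = 165.0  # nominal chopstick length at 1 px/mm
_UPPER_ANGLE0 = np.pi * 1.06  # resting direction, pointing left/slightly down
_LOWER_ANGLE_OFFSET = 0.0  # sticks rest parallel (held open) with a vertical gap
_TIP_FRACTION = 0.72  # fraction of length ahead of the grip point


def _rotate_about(points: np.ndarray, pivot: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Rotate ``points`` (..., k, 2) about ``pivot`` (2,) by angles ``theta`` (...,)."""
    c, s = np.cos(theta), np.sin(theta)
    rel = points - pivot
    x = c[..., None] * rel[..., 0] - s[..., None] * rel[..., 1]
    y = s[..., None] * rel[..., 0] + c[..., None] * rel[..., 1]
    return np.stack([x, y], axis=-1) + pivot


def _point_line_distance(p: np.ndarray, seg: np.ndarray) -> np.ndarray:
    """Unsigned distance from points (..., 2) to the infinite line through seg (..., 2, 2).

    Kept local so the simulator's analytic ground truth is independent of the
    feature module it is used to test.
    """
    a, b = seg[..., 0, :], seg[..., 1, :]
    d = b - a
    norm = np.hypot(d[..., 0], d[..., 1])
    cross = d[..., 0] * (p[..., 1] - a[..., 1]) - d[..., 1] * (p[..., 0] - a[..., 0])
    return np.abs(cross) / norm


def generate_grip_sequence(
    archetype: GripArchetype | str,
    protocol: TrialProtocol | None = None,
    *,
    hand_length_px: float = DEFAULT_HAND_LENGTH_PX,
    origin: tuple[float, float] = DEFAULT_ORIGIN,
    seed: int | None = None,
) -> GripSequence:
    """Simulate one trial for a grip archetype.

    Returns a :class:`GripSequence` of ``duration_s * fps`` frames whose
    fingertip apertures oscillate at the protocol's open/close frequency.
    Gaussian landmark jitter is added at ``protocol.noise_sd_px``;
    chopstick detection dropouts are injected at ``protocol.dropout_rate``
    (dropped frames have source ``"missing"``).  The noiseless analytic
    values of the four grip distances are stored in ``meta["truth_abcd"]``,
    computed on the same final coordinates with an independent formula.

    Deterministic for a fixed seed (``seed`` argument wins over
    ``protocol.seed``).
    """
    if isinstance(archetype, str):
        archetype = ARCHETYPES[archetype]
    protocol = protocol or TrialProtocol()
    if seed is None:
        seed = protocol.seed
    rng = np.random.default_rng(seed)

    n = protocol.n_frames
    t = np.arange(n) / protocol.fps
    omega = 2 * np.pi * protocol.open_close_hz
    org = np.asarray(origin, dtype=float)

    base = BASE_HAND * hand_length_px + org  # (21, 2)
    landmarks = np.broadcast_to(base, (n, 21, 2)).copy()

    # sinusoidal flexion about each finger's proximal joint
    for fi, finger in enumerate(FINGER_ORDER):
        amp = np.deg2rad(archetype.amplitude_deg[fi])
        if amp == 0:
            continue
        theta = amp * 0.5 * (1 - np.cos(omega * t + archetype.phase[fi]))
        if finger == "I":
            theta = -theta  # thumb opposes the fingers
        idx = list(FINGER_INDICES[finger])
        pivot = base[idx[0]]
        landmarks[:, idx[1:], :] = _rotate_about(
            np.broadcast_to(base[idx[1:]], (n, 3, 2)), pivot, theta
        )

    # chopsticks -----------------------------------------------------------
    jitter = (
        rng.uniform(-archetype.contact_jitter_px, archetype.contact_jitter_px, size=2)
        if archetype.contact_jitter_px > 0
        else np.zeros(2)
    )
    # upper stick is pinched between the tips of fingers I and II, offset a
    # little toward the palm so fingertips stay on one side of the line;
    # lower stick runs from the thumb web across finger IV's first knuckle
    grip_upper = 0.5 * (base[4] + base[8]) + np.array([0.0, 8.0]) + jitter
    grip_lower = 0.5 * (base[3] + base[16]) + np.array([0.0, 22.0]) + jitter

    if archetype.coupling:
        coupled = [FINGER_ORDER.index(f) for f in archetype.coupling]
        mean_amp = np.deg2rad(np.mean([archetype.amplitude_deg[i] for i in coupled]))
        beta_amp = 0.35 * mean_amp  # stick swings less than the fingers driving it
    else:
        beta_amp = 0.0
    beta = _UPPER_ANGLE0 + beta_amp * np.sin(omega * t)
    u_dir = np.stack([np.cos(beta), np.sin(beta)], axis=-1)
    tip_len = _TIP_FRACTION * CHOPSTICK_LENGTH_PX
    butt_len = CHOPSTICK_LENGTH_PX - tip_len
    upper = np.stack(
        [grip_upper + u_dir * tip_len, grip_upper - u_dir * butt_len], axis=1
    )  # (n, 2, 2)

    gamma0 = _UPPER_ANGLE0 + _LOWER_ANGLE_OFFSET
    if archetype.lower_support:
        gamma = np.full(n, gamma0)
        lower_shift = np.zeros((n, 2))
    else:
        # unsupported lower chopstick wobbles in angle and position
        gamma = gamma0 + np.deg2rad(2.0) * np.sin(omega * t + np.pi / 3)
        lower_shift = 2.0 * np.stack(
            [np.cos(omega * t + np.pi / 3), np.sin(omega * t + np.pi / 3)], axis=-1
        )
    l_dir = np.stack([np.cos(gamma), np.sin(gamma)], axis=-1)
    l_grip = grip_lower + lower_shift
    lower = np.stack([l_grip + l_dir * tip_len, l_grip - l_dir * butt_len], axis=1)

    # whole-hand sway (palm-driven styles): hand and both chopsticks translate
    if archetype.hand_sway_px > 0:
        sway = archetype.hand_sway_px * np.stack(
            [0.3 * np.sin(omega * t), np.sin(omega * t)], axis=-1
        )
        landmarks += sway[:, None, :]
        upper += sway[:, None, :]
        lower += sway[:, None, :]

    # landmark jitter (pose-estimator noise)
    if protocol.noise_sd_px > 0:
        landmarks = landmarks + rng.normal(0, protocol.noise_sd_px, size=landmarks.shape)

    # analytic ground-truth distances on the final coordinates
    from .datatypes import FINGERTIP_II, FINGERTIP_III, FINGERTIP_IV, FIRST_JOINT_III

    truth = np.column_stack(
        [
            _point_line_distance(landmarks[:, FINGERTIP_II], upper),
            _point_line_distance(landmarks[:, FIRST_JOINT_III], upper),
            _point_line_distance(landmarks[:, FINGERTIP_III], lower),
            np.hypot(
                *(landmarks[:, FINGERTIP_III] - landmarks[:, FINGERTIP_IV]).T
            ),
        ]
    )

    sources = np.full(n, "detected", dtype=object)
    if protocol.dropout_rate > 0:
        dropped = rng.random(n) < protocol.dropout_rate
        sources[dropped] = "missing"
        upper = upper.copy()
        lower = lower.copy()
        upper[dropped] = np.nan
        lower[dropped] = np.nan

    return GripSequence(
        t=t,
        landmarks=landmarks,
        upper=upper,
        lower=lower,
        sources=sources,
        label=archetype.binary_label,
        archetype=archetype.name,
        seed=seed,
        fps=protocol.fps,
        meta={"truth_abcd": truth, "protocol": protocol},
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

#: default tape colors (RGB): upper chopstick blue, lower green
DEFAULT_TAPE_COLORS = {"upper": (0, 0, 255), "lower": (0, 200, 0)}
DEFAULT_BACKGROUND = (255, 255, 255)  # white cloth


def _draw_segment(img: np.ndarray, seg: np.ndarray, color, thickness: float) -> None:
    from skimage.draw import polygon

    a, b = seg[0], seg[1]
    d = b - a
    norm = np.hypot(*d)
    if norm == 0:
        return
    perp = np.array([-d[1], d[0]]) / norm * (thickness / 2)
    corners = np.array([a + perp, b + perp, b - perp, a - perp])
    rr, cc = polygon(corners[:, 1], corners[:, 0], shape=img.shape[:2])
    img[rr, cc] = color


def render_frames(
    sequence: GripSequence,
    frame_size: tuple[int, int] = (480, 480),
    tape_colors: dict | None = None,
    *,
    thickness: float = 5.0,
    background=DEFAULT_BACKGROUND,
) -> np.ndarray:
    """Rasterize a sequence's chopsticks into an image stack.

    Each frame draws the upper chopstick in the upper-tape color and the
    lower chopstick in the lower-tape color on a plain background; dropout
    frames (source ``"missing"``) omit the chopsticks entirely.  Returns a
    ``(n, H, W, 3)`` uint8 stack.
    """
    if len(sequence) == 0:
        raise RenderError("cannot render an empty sequence")
    tape_colors = tape_colors or DEFAULT_TAPE_COLORS
    h, w = int(frame_size[0]), int(frame_size[1])

    xy = sequence.landmarks.reshape(-1, 2)
    sticks = np.concatenate(
        [sequence.upper.reshape(-1, 2), sequence.lower.reshape(-1, 2)]
    )
    sticks = sticks[np.isfinite(sticks).all(axis=1)]
    allpts = np.concatenate([xy[np.isfinite(xy).all(axis=1)], sticks])
    if (allpts < 0).any() or (allpts[:, 0] >= w).any() or (allpts[:, 1] >= h).any():
        raise RenderError(
            f"frame size {frame_size} too small to contain the landmarks and "
            "chopsticks; enlarge the frame or move the origin"
        )

    stack = np.empty((len(sequence), h, w, 3), dtype=np.uint8)
    stack[...] = np.asarray(background, dtype=np.uint8)
    for i in range(len(sequence)):
        if str(sequence.sources[i]) == "missing":
            continue
        _draw_segment(stack[i], sequence.upper[i], tape_colors["upper"], thickness)
        _draw_segment(stack[i], sequence.lower[i], tape_colors["lower"], thickness)
    return stack


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

#: nontraditional composition of the study cohort (three-finger : palm : other)
DEFAULT_CLASS_MIX = {"three_finger": 49, "palm": 20, "other": 32}


def _allocate(n: int, weights: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n among classes by weight."""
    total = sum(weights.values())
    raw = {k: n * v / total for k, v in weights.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def make_dataset(
    n_traditional: int = 60,
    n_nontraditional: int = 103,
    class_mix: dict[str, float] | None = None,
    protocol: TrialProtocol | None = None,
    *,
    seed: int | None = None,
) -> list[GripSequence]:
    """Generate a labeled trial collection.

    Defaults emulate the analyzed video corpus: 60 traditional-grip trials
    and 103 with a different grip, the nontraditional trials split across
    three-finger, palm and other archetypes in the cohort's observed
    proportions.  Per-sequence seeds are spawned from ``seed`` and recorded
    on each sequence, so the dataset is bit-identical across runs.
    """
    if n_traditional <= 0 or n_nontraditional <= 0:
        raise ConfigurationError("class counts must be positive")
    class_mix = class_mix if class_mix is not None else dict(DEFAULT_CLASS_MIX)
    if not class_mix:
        raise ConfigurationError("class_mix must not be empty")
    for k in class_mix:
        if k not in ARCHETYPES or k == "four_finger":
            raise ConfigurationError(f"class_mix key {k!r} is not a nontraditional archetype")
    protocol = protocol or TrialProtocol()
    rng = np.random.default_rng(seed)

    plan = [("four_finger", None)] * n_traditional
    for name, count in _allocate(n_nontraditional, class_mix).items():
        plan += [(name, None)] * count

    dataset = []
    for name, _ in plan:
        child_seed = int(rng.integers(2**31))
        dataset.append(generate_grip_sequence(name, protocol, seed=child_seed))
    return dataset


# ---------------------------------------------------------------------------
# Synthetic survey cohort
# ---------------------------------------------------------------------------

#: cohort marginals used as generator defaults (study conditions)
COHORT = {
    "n": 165,
    "p_age7": 51 / 165,
    "p_boy": 75 / 165,
    "p_cohabitation": 0.30,
    "p_training": 0.80,
    "dcdq_mean": 51.25,
    "dcdq_sd": 9.93,
    "maternal_age_mean": 37.88,
    "maternal_age_sd": 6.11,
    "p_taught": 136 / 165,
    "p_knows": 152 / 165,
    "p_can_use": 117 / 165,
    "class_counts": {"four_finger": 64, "three_finger": 49, "palm": 20, "other": 32},
    "rater_agreement": 0.98,
}

SURVEY_PREDICTORS = ("const", "age", "sex", "cohabitation", "training", "dcdq_total")
SURVEY_CONTRASTS = ("three_finger", "palm_other")


def _default_coefficients() -> dict[tuple[str, str], float]:
    cc = COHORT["class_counts"]
    coef = {(p, c): 0.0 for p in SURVEY_PREDICTORS for c in SURVEY_CONTRASTS}
    coef[("const", "three_finger")] = float(np.log(cc["three_finger"] / cc["four_finger"]))
    coef[("const", "palm_other")] = float(
        np.log((cc["palm"] + cc["other"]) / cc["four_finger"])
    )
    return coef


def make_survey_table(
    n: int = COHORT["n"],
    coefficients: dict[tuple[str, str], float] | None = None,
    missing_rate: float = 0.0,
    seed: int | None = None,
):
    """Generate a synthetic questionnaire table.

    The grip class is drawn from a multinomial logit over the three-level
    outcome (four-finger reference; three-finger; palm+other) with the given
    log-odds ``coefficients``, keyed ``(predictor, contrast)`` with
    predictors among :data:`SURVEY_PREDICTORS` and contrasts among
    :data:`SURVEY_CONTRASTS`.  Unset coefficients default to zero slopes
    with intercepts matching the cohort's class mix.  Covariates follow the
    cohort marginals: age 6/7, sex, grandparent cohabitation, prior
    training, DCDQ totals ~ Normal(51.25, 9.93) truncated to [15, 75].
    Missing cells are inserted completely at random at ``missing_rate``
    (DCDQ items and the two household flags; class labels stay observed).

    Returns a pandas DataFrame, one row per child.
    """
    import pandas as pd
    from scipy import stats

    if n < 10:
        raise ConfigurationError("survey table needs n >= 10")
    if not 0 <= missing_rate < 1:
        raise ConfigurationError("missing_rate must lie in [0, 1)")
    coef = _default_coefficients()
    if coefficients:
        for key, value in coefficients.items():
            if tuple(key) not in coef:
                raise ConfigurationError(
                    f"unknown coefficient key {key!r}; predictors are "
                    f"{SURVEY_PREDICTORS}, contrasts {SURVEY_CONTRASTS}"
                )
            coef[tuple(key)] = float(value)

    rng = np.random.default_rng(seed)
    age = 6 + (rng.random(n) < COHORT["p_age7"]).astype(int)
    sex = np.where(rng.random(n) < COHORT["p_boy"], "boy", "girl")
    cohab = (rng.random(n) < COHORT["p_cohabitation"]).astype(int)
    training = (rng.random(n) < COHORT["p_training"]).astype(int)

    lo, hi = 15, 75
    m, s = COHORT["dcdq_mean"], COHORT["dcdq_sd"]
    total = stats.truncnorm.rvs(
        (lo - m) / s, (hi - m) / s, loc=m, scale=s, size=n, random_state=rng
    )
    total = np.clip(np.round(total).astype(int), lo, hi)
    items = np.empty((n, 15), dtype=float)
    for i in range(n):
        base = total[i] // 15
        row = np.full(15, base)
        extra = rng.choice(15, size=total[i] - 15 * base, replace=False)
        row[extra] += 1
        items[i] = row

    # outcome: multinomial logit on [1, age, sex, cohab, training, dcdq_total]
    design = np.column_stack(
        [np.ones(n), age, (sex == "boy").astype(int), cohab, training, total]
    )
    # center non-const predictors inside the intercept so the default
    # intercepts keep the intended mix when slopes are nonzero
    centers = np.array([0.0, 6.0, 0.0, 0.0, 0.0, m])
    eta = np.zeros((n, 3))
    for j, contrast in enumerate(SURVEY_CONTRASTS, start=1):
        b = np.array([coef[(p, contrast)] for p in SURVEY_PREDICTORS])
        eta[:, j] = (design - centers) @ b
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    draw = (rng.random(n)[:, None] > np.cumsum(p, axis=1)).sum(axis=1)

    cc = COHORT["class_counts"]
    p_palm = cc["palm"] / (cc["palm"] + cc["other"])
    grip = np.empty(n, dtype=object)
    grip[draw == 0] = "four_finger"
    grip[draw == 1] = "three_finger"
    pm = draw == 2
    grip[pm] = np.where(rng.random(pm.sum()) < p_palm, "palm", "other")

    # two raters with high but imperfect agreement
    rater1 = grip.copy()
    rater2 = grip.copy()
    disagree = rng.random(n) >= COHORT["rater_agreement"]
    for i in np.where(disagree)[0]:
        others = [g for g in GRIP_CLASSES if g != grip[i]]
        rater2[i] = others[rng.integers(len(others))]

    mat_age = stats.truncnorm.rvs(
        (26 - COHORT["maternal_age_mean"]) / COHORT["maternal_age_sd"],
        (49 - COHORT["maternal_age_mean"]) / COHORT["maternal_age_sd"],
        loc=COHORT["maternal_age_mean"],
        scale=COHORT["maternal_age_sd"],
        size=n,
        random_state=rng,
    )

    df = pd.DataFrame(
        {
            "child_id": np.arange(1, n + 1),
            "age": age,
            "sex": sex,
            "cohabitation": cohab.astype(float),
            "training": training.astype(float),
            **{f"dcdq_{k + 1}": items[:, k] for k in range(15)},
            "grip_class": grip,
            "rater_1": rater1,
            "rater_2": rater2,
            "maternal_age": np.round(mat_age, 1),
            "maternal_taught": (rng.random(n) < COHORT["p_taught"]).astype(float),
            "maternal_knows": (rng.random(n) < COHORT["p_knows"]).astype(float),
            "maternal_can_use": (rng.random(n) < COHORT["p_can_use"]).astype(float),
        }
    )

    if missing_rate > 0:
        maskable = [f"dcdq_{k + 1}" for k in range(15)] + ["cohabitation", "training"]
        mask = rng.random((n, len(maskable))) < missing_rate
        for j, col in enumerate(maskable):
            df.loc[mask[:, j], col] = np.nan
    return df
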