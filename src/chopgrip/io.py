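"""Readers and writers for the artifact formats.

Formats are deliberately plain: CSV (UTF-8, comma, header row, '.' decimal,
times in seconds as floats) and JSON for sequences, poses, features, models
and manifests; PNG stacks for rendered frames; CSV/XLSX for survey tables.
Every writer/reader pair round-trips losslessly, and no reader mutates its
input on disk.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GripSequence, HandLandmarkFrame, N_LANDMARKS
from .errors import SchemaError

LANDMARK_COLS = [c for i in range(N_LANDMARKS) for c in (f"x{i}", f"y{i}")]
POSE_COLS = [
    "upper_x1",
    "upper_y1",
    "upper_x2",
    "upper_y2",
    "lower_x1",
    "lower_y1",
    "lower_x2",
    "lower_y2",
]


# ---------------------------------------------------------------------------
# Sequences and landmarks
# ---------------------------------------------------------------------------


def sequence_to_frame(seq: GripSequence) -> pd.DataFrame:
    """One row per frame: t, 42 landmark coords, 8 chopstick coords, source."""
    df = pd.DataFrame({"t": seq.t})
    lm = seq.landmarks.reshape(len(seq), -1)
    for j, col in enumerate(LANDMARK_COLS):
        df[col] = lm[:, j]
    sticks = np.concatenate(
        [seq.upper.reshape(len(seq), 4), seq.lower.reshape(len(seq), 4)], axis=1
    )
    for j, col in enumerate(POSE_COLS):
        df[col] = sticks[:, j]
    df["source"] = [str(s) for s in seq.sources]
    return df


def write_sequence(seq: GripSequence, path) -> Path:
    path = Path(path)
    sequence_to_frame(seq).to_csv(path, index=False)
    return path


def read_sequence(path) -> GripSequence:
    df = pd.read_csv(path)
    missing = [c for c in ["t", *LANDMARK_COLS, *POSE_COLS, "source"] if c not in df]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing[:4]}...")
    n = len(df)
    fps = 1.0 / np.median(np.diff(df["t"])) if n > 1 else 30.0
    return GripSequence(
        t=df["t"].to_numpy(float),
        landmarks=df[LANDMARK_COLS].to_numpy(float).reshape(n, N_LANDMARKS, 2),
        upper=df[POSE_COLS[:4]].to_numpy(float).reshape(n, 2, 2),
        lower=df[POSE_COLS[4:]].to_numpy(float).reshape(n, 2, 2),
        sources=df["source"].to_numpy(object),
        fps=float(round(fps, 6)),
    )


def write_landmark_series(frames: list[HandLandmarkFrame], path) -> Path:
    """Landmark-only series as CSV (t, x0, y0, ..., x20, y20) or JSON."""
    path = Path(path)
    if path.suffix == ".json":
        payload = [
            {"t": f.t, "points": f.points.tolist(), "handedness": f.handedness}
            for f in frames
        ]
        path.write_text(json.dumps(payload))
        return path
    rows = [{"t": f.t, **dict(zip(LANDMARK_COLS, f.points.ravel()))} for f in frames]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_landmark_series(path) -> list[HandLandmarkFrame]:
    """Read a landmark series (CSV or JSON), validating the 21-point schema.

    Schema violations are reported with the offending row number.
    """
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        frames = []
        for i, row in enumerate(payload):
            pts = np.asarray(row["points"], dtype=float)
            if pts.shape != (N_LANDMARKS, 2):
                raise SchemaError(
                    f"{path}: row {i} has {pts.shape[0]} points, expected {N_LANDMARKS}"
                )
            frames.append(
                HandLandmarkFrame(
                    t=float(row["t"]), points=pts, handedness=row.get("handedness", "right")
                )
            )
    else:
        df = pd.read_csv(path)
        missing = [c for c in ["t", *LANDMARK_COLS] if c not in df]
        if missing:
            raise SchemaError(
                f"{path}: columns for {len(missing)} coordinates missing "
                f"(first: {missing[0]}); expected {N_LANDMARKS} points per row"
            )
        bad = df[["t", *LANDMARK_COLS]].isna().any(axis=1)
        if bad.any():
            raise SchemaError(f"{path}: row {int(bad.idxmax())} has missing values")
        frames = [
            HandLandmarkFrame(
                t=float(r["t"]),
                points=r[LANDMARK_COLS].to_numpy(float).reshape(N_LANDMARKS, 2),
            )
            for _, r in df.iterrows()
        ]
    frames.sort(key=lambda f: f.t)
    return frames


def write_poses(poses, path) -> Path:
    """Per-frame chopstick pose CSV (frame, 8 endpoint coords, source)."""
    rows = []
    for p in poses:
        coords = (
            np.full(8, np.nan)
            if p.missing
            else np.concatenate([p.upper.ravel(), p.lower.ravel()])
        )
        rows.append({"frame": p.frame_index, **dict(zip(POSE_COLS, coords)), "source": p.source})
    pd.DataFrame(rows).to_csv(Path(path), index=False)
    return Path(path)


def read_poses(path):
    from .datatypes import ChopstickPose

    df = pd.read_csv(path)
    poses = []
    for _, r in df.iterrows():
        if r["source"] == "missing":
            poses.append(ChopstickPose(None, None, "missing", int(r["frame"])))
        else:
            poses.append(
                ChopstickPose(
                    r[POSE_COLS[:4]].to_numpy(float).reshape(2, 2),
                    r[POSE_COLS[4:]].to_numpy(float).reshape(2, 2),
                    str(r["source"]),
                    int(r["frame"]),
                )
            )
    return poses


def write_features(frames, path) -> Path:
    """Per-frame feature CSV: t, a, b, c, d, coordinates, filled flag."""
    rows = []
    for fr in frames:
        row = {"t": fr.t, "a": fr.a, "b": fr.b, "c": fr.c, "d": fr.d}
        row.update(dict(zip(LANDMARK_COLS, fr.landmark_xy)))
        row.update(dict(zip(POSE_COLS, fr.chopstick_xy)))
        row["filled"] = int(fr.filled)
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), index=False)
    return Path(path)


def write_frames_png(stack: np.ndarray, out_dir) -> list[Path]:
    """Write an image stack as zero-padded PNG files frame_0000.png, ..."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(stack):
        p = out_dir / f"frame_{i:04d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def read_frames_png(in_dir) -> np.ndarray:
    import imageio.v3 as iio

    paths = sorted(Path(in_dir).glob("*.png"))
    if not paths:
        raise SchemaError(f"no PNG frames found in {in_dir}")
    return np.stack([iio.imread(p) for p in paths])


# ---------------------------------------------------------------------------
# Survey tables
# ---------------------------------------------------------------------------


def read_survey_table(path, column_map: dict | str | None = None) -> pd.DataFrame:
    """Read a survey workbook (XLSX) or CSV, renaming columns to the
    canonical schema via ``column_map`` ({canonical: file_header} dict or a
    YAML file of the same)."""
    path = Path(path)
    df = pd.read_excel(path) if path.suffix in (".xlsx", ".xls") else pd.read_csv(path)
    if column_map is not None:
        if isinstance(column_map, (str, Path)):
            import yaml

            column_map = yaml.safe_load(Path(column_map).read_text())
        rename = {v: k for k, v in column_map.items()}
        missing = [v for v in rename if v not in df.columns]
        if missing:
            raise SchemaError(f"{path}: mapped columns not found: {missing}")
        df = df.rename(columns=rename)
    return df


def write_survey_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    if path.suffix in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Model serialization (JSON)
# ---------------------------------------------------------------------------


def model_to_json(clf, path=None) -> dict:
    """Serialize a fitted :class:`~chopgrip.pipeline.GripClassifier` to JSON:
    tree structure, retained features, hyperparameters and a config hash."""
    t = clf.tree_.tree_
    params = clf.get_params()
    payload = {
        "format": "chopgrip-tree",
        "version": 1,
        "params": params,
        "config_hash": hashlib.sha256(
            json.dumps(params, sort_keys=True).encode()
        ).hexdigest()[:16],
        "classes": [str(c) for c in clf.classes_],
        "n_features_in": int(clf.n_features_in_),
        "retained_mask": clf.retained_mask_.astype(int).tolist(),
        "stage1_importances": clf.stage1_importances_.tolist(),
        "tree": {
            "children_left": t.children_left.tolist(),
            "children_right": t.children_right.tolist(),
            "feature": t.feature.tolist(),
            "threshold": t.threshold.tolist(),
            "value": t.value[:, 0, :].tolist(),
        },
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=1))
    return payload


class LoadedGripModel:
    """A JSON-deserialized grip model: pure-python tree traversal."""

    def __init__(self, payload: dict):
        if payload.get("format") != "chopgrip-tree":
            raise SchemaError("not a chopgrip model file")
        self.payload = payload
        self.classes_ = np.array(payload["classes"])
        self.retained_mask_ = np.array(payload["retained_mask"], dtype=bool)
        self.n_features_in_ = payload["n_features_in"]
        self._t = payload["tree"]

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.n_features_in_:
            raise SchemaError(
                f"model expects {self.n_features_in_} features, got {X.shape[1]}"
            )
        Xr = X[:, self.retained_mask_]
        left, right = self._t["children_left"], self._t["children_right"]
        feat, thr, value = self._t["feature"], self._t["threshold"], self._t["value"]
        out = np.empty((len(Xr), len(self.classes_)))
        for i, x in enumerate(Xr):
            node = 0
            while left[node] != -1:
                node = left[node] if x[feat[node]] <= thr[node] else right[node]
            v = np.asarray(value[node], dtype=float)
            out[i] = v / v.sum()
        return out

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def model_from_json(path_or_payload) -> LoadedGripModel:
    payload = (
        path_or_payload
        if isinstance(path_or_payload, dict)
        else json.loads(Path(path_or_payload).read_text())
    )
    return LoadedGripModel(payload)


# ---------------------------------------------------------------------------
# Run configuration and manifests
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Top-level configuration; one seed feeds every random stage."""

    seed: int = 1234
    feature_mode: str = "perpendicular"
    normalization: str = "none"
    max_gap: int = 5
    classifier: dict = field(default_factory=dict)
    cv_folds: int = 5
    colors: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    column_map: str | None = None
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def write_outputs(results: dict, config: RunConfig, out_dir=None) -> Path:
    """Write result tables/objects plus a manifest enabling exact re-runs.

    ``results`` maps file names to DataFrames (written as CSV), dicts/lists
    (JSON) or GripSequences (CSV).  The manifest records every written
    file, the seed, the config hash and package versions.
    """
    out_dir = Path(out_dir or config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in results.items():
        p = out_dir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(p, index=isinstance(obj.index, pd.Index) and obj.index.name is not None)
        elif isinstance(obj, GripSequence):
            write_sequence(obj, p)
        else:
            p.write_text(json.dumps(obj, indent=1, default=_jsonable))
        written.append(name)

    import sklearn
    import statsmodels

    from . import __version__

    manifest = {
        "files": written,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "versions": {
            "chopgrip": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir / "manifest.json"


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")
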