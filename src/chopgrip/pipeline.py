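"""Sequence-level grip classification.

Pipeline order: augment raw sequences -> compute per-frame features ->
summarize each trial -> classify at the sequence level, one verdict per
video.  Each of the 14 per-frame channels (the four grip distances a-d and
the 10 fingertip coordinates) is summarized by three statistics: its mean,
its standard deviation, and CO_f1ecac — the first lag at which the
autocorrelation function decays below 1/e, a timescale of signal memory
that separates rhythmically moving fingers from noise-dominated ones.

The classifier is a decision tree with importance-based feature weighting,
realized as a two-stage fit: a first tree ranks all summary features by
impurity importance, features below an importance quantile (default the
median) are dropped, and the tree is refit on the retained set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .datatypes import GripSequence
from .errors import SequenceError, ZeroVarianceError
from .features import DEFAULT_MAX_GAP, feature_matrix

E_INV = 1.0 / np.e

#: per-frame channels entering the sequence summary
CHANNELS = (
    "a",
    "b",
    "c",
    "d",
    "tipI_x",
    "tipI_y",
    "tipII_x",
    "tipII_y",
    "tipIII_x",
    "tipIII_y",
    "tipIV_x",
    "tipIV_y",
    "tipV_x",
    "tipV_y",
)
STATS = ("co_f1ecac", "mean", "sd")
SUMMARY_FEATURE_NAMES = tuple(f"{ch}_{st}" for ch in CHANNELS for st in STATS)


# ---------------------------------------------------------------------------
# CO_f1ecac
# ---------------------------------------------------------------------------


def autocorrelation(series: np.ndarray) -> np.ndarray:
    """Biased sample ACF: mean-removed, divide-by-n autocovariance
    normalized by lag 0.  Computed via FFT (Wiener-Khinchin)."""
    x = np.asarray(series, dtype=float)
    if np.ptp(x) == 0:
        raise ZeroVarianceError("constant series has no autocorrelation")
    x = x - x.mean()
    n = len(x)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f))[:n] / n
    return acov / acov[0]


def co_f1ecac(series: np.ndarray) -> float:
    """First 1/e crossing of the autocorrelation function, in lags.

    The crossing is linearly interpolated between the integer lags
    bracketing 1/e, so the value is fractional.  If the ACF never falls
    below 1/e within the available lags, the maximum lag used (length - 1)
    is returned as a sentinel.  Raises :class:`ZeroVarianceError` for a
    constant series and :class:`SequenceError` for fewer than 3 samples.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 3:
        raise SequenceError("co_f1ecac needs at least 3 samples")
    ac = autocorrelation(x)
    below = np.nonzero(ac[1:] < E_INV)[0]
    if len(below) == 0:
        return float(len(x) - 1)
    i = int(below[0])  # crossing between lag i and i+1
    return i + (E_INV - ac[i]) / (ac[i + 1] - ac[i])


# ---------------------------------------------------------------------------
# Sequence summaries
# ---------------------------------------------------------------------------


@dataclass
class SequenceSummary:
    """Fixed-length summary of one trial.

    ``values`` maps each summary feature name (channel x statistic, see
    :data:`SUMMARY_FEATURE_NAMES`) to its value; zero-variance channels get
    the CO_f1ecac sentinel (length - 1) rather than an error.
    """

    values: dict = field(default_factory=dict)
    length: int = 0
    filled_fraction: float = 0.0
    label: str | None = None

    def vector(self) -> np.ndarray:
        return np.array([self.values[name] for name in SUMMARY_FEATURE_NAMES])


def summarize_sequence(
    sequence: GripSequence, max_gap: int = DEFAULT_MAX_GAP
) -> SequenceSummary:
    """Summarize one trial into the fixed classifier feature vector."""
    cols = feature_matrix(sequence, max_gap=max_gap)
    n = len(cols["t"])
    if n < 3:
        raise SequenceError(f"sequence too short after gap handling ({n} frames)")
    values = {}
    for ch in CHANNELS:
        x = cols[ch]
        try:
            values[f"{ch}_co_f1ecac"] = co_f1ecac(x)
        except ZeroVarianceError:
            values[f"{ch}_co_f1ecac"] = float(n - 1)
        values[f"{ch}_mean"] = float(x.mean())
        values[f"{ch}_sd"] = float(x.std())
    return SequenceSummary(
        values=values,
        length=n,
        filled_fraction=float(cols["filled"].mean()),
        label=sequence.label,
    )


class SequenceSummarizer(TransformerMixin, BaseEstimator):
    """Stateless transformer: list of :class:`GripSequence` -> summary matrix."""

    def __init__(self, max_gap: int = DEFAULT_MAX_GAP):
        self.max_gap = max_gap

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        return np.vstack(
            [summarize_sequence(seq, max_gap=self.max_gap).vector() for seq in X]
        )


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def augment_samples(
    samples: list[GripSequence],
    labels: list[str] | None = None,
    factor_range: tuple[float, float] = (0.9, 1.1),
    shift_range: tuple[float, float] = (-20.0, 20.0),
    seed: int | None = None,
) -> tuple[list[GripSequence], list[str]]:
    """Double the traditional class by scaled/translated copies.

    Each traditional-grip raw sequence gets exactly one transformed copy: a
    uniform scale drawn from ``factor_range`` about the sequence's mean
    wrist position, plus a translation drawn per axis from ``shift_range``.
    Nontraditional samples are passed through untouched.  Augmentation
    operates on raw landmark+chopstick sequences, before feature
    computation.
    """
    if labels is None:
        labels = [s.label for s in samples]
    if len(labels) != len(samples):
        raise ValueError("labels and samples must have equal length")
    rng = np.random.default_rng(seed)
    out, out_labels = list(samples), list(labels)
    n_trad = sum(lab == "traditional" for lab in labels)
    if n_trad == 0:
        warnings.warn("no traditional samples to augment; returning input unchanged")
        return out, out_labels
    for seq, lab in zip(samples, labels):
        if lab != "traditional":
            continue
        s = rng.uniform(*factor_range)
        shift = rng.uniform(shift_range[0], shift_range[1], size=2)
        center = seq.landmarks[:, 0, :].mean(axis=0)  # mean wrist position
        copy = seq.copy()
        copy.landmarks = (copy.landmarks - center) * s + center + shift
        copy.upper = (copy.upper - center) * s + center + shift
        copy.lower = (copy.lower - center) * s + center + shift
        copy.meta["augmented"] = True
        if "truth_abcd" in copy.meta:
            copy.meta["truth_abcd"] = copy.meta["truth_abcd"] * s
        out.append(copy)
        out_labels.append(lab)
    return out, out_labels


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------


class GripClassifier(ClassifierMixin, BaseEstimator):
    """Decision tree with importance-quantile feature selection.

    Stage 1 fits a tree on all summary features and records impurity-based
    importances; features whose importance falls strictly below the
    ``importance_quantile`` of the importance distribution are dropped and
    the tree is refit on the survivors.  Shallow defaults (depth 5, minimum
    leaf 5) resist overfitting at the ~160-trial scale of a school cohort.

    Attributes (after fit)
    ----------------------
    classes_ : ndarray of class labels
    stage1_importances_ : importances of all input features
    retained_mask_ : boolean mask of retained features
    feature_importances_ : importances of the refit tree, on the full
        feature axis (zeros at dropped positions)
    tree_ : the refit :class:`~sklearn.tree.DecisionTreeClassifier`
    """

    def __init__(
        self,
        criterion: str = "gini",
        max_depth: int | None = 5,
        min_samples_leaf: int = 5,
        importance_quantile: float = 0.5,
        random_state: int = 1234,
    ):
        self.criterion = criterion
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.importance_quantile = importance_quantile
        self.random_state = random_state

    def _make_tree(self) -> DecisionTreeClassifier:
        return DecisionTreeClassifier(
            criterion=self.criterion,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
        )

    def fit(self, X, y):
        from sklearn.utils.multiclass import unique_labels
        from sklearn.utils.validation import validate_data

        X, y = validate_data(self, X, y)
        self.classes_ = unique_labels(y)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        counts = np.bincount(np.searchsorted(self.classes_, y))
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 samples")

        stage1 = self._make_tree().fit(X, y)
        imp = stage1.feature_importances_
        threshold = np.quantile(imp, self.importance_quantile)
        retained = imp >= threshold
        if not retained.any():  # degenerate: keep everything
            retained = np.ones_like(retained, dtype=bool)
        self.stage1_importances_ = imp
        self.retained_mask_ = retained
        self.tree_ = self._make_tree().fit(X[:, retained], y)
        self.feature_importances_ = np.zeros(X.shape[1])
        self.feature_importances_[retained] = self.tree_.feature_importances_
        return self

    def predict(self, X):
        from sklearn.utils.validation import validate_data

        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.tree_.predict(X[:, self.retained_mask_])

    def predict_proba(self, X):
        from sklearn.utils.validation import validate_data

        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.tree_.predict_proba(X[:, self.retained_mask_])

    @property
    def retained_feature_names_(self):
        check_is_fitted(self)
        if self.n_features_in_ == len(SUMMARY_FEATURE_NAMES):
            return [
                n for n, keep in zip(SUMMARY_FEATURE_NAMES, self.retained_mask_) if keep
            ]
        return list(np.nonzero(self.retained_mask_)[0])


def train_classifier(
    summaries: list[SequenceSummary] | np.ndarray,
    labels: list[str],
    config: dict | None = None,
) -> GripClassifier:
    """Fit a :class:`GripClassifier` on sequence summaries (thin wrapper)."""
    X = (
        np.vstack([s.vector() for s in summaries])
        if summaries and isinstance(summaries[0], SequenceSummary)
        else np.asarray(summaries)
    )
    return GripClassifier(**(config or {})).fit(X, np.asarray(labels))


def predict(model: GripClassifier, summary: SequenceSummary | np.ndarray):
    """Predict the grip label for one summarized trial."""
    x = summary.vector() if isinstance(summary, SequenceSummary) else np.asarray(summary)
    return model.predict(x.reshape(1, -1))[0]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate_metrics(
    predicted, truth, positive: str = "traditional"
) -> dict[str, float]:
    """Accuracy, precision, recall and F1 with the traditional grip positive.

    Precision (and F1) are reported as 0, with a warning, when no positives
    are predicted although positives exist.
    """
    from sklearn.metrics import accuracy_score, precision_recall_fscore_support

    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    if len(truth) == 0:
        raise ValueError("cannot evaluate empty label lists")
    p, r, f1, _ = precision_recall_fscore_support(
        truth, predicted, pos_label=positive, average="binary", zero_division="warn"
    )
    return {
        "accuracy": float(accuracy_score(truth, predicted)),
        "precision": float(p),
        "recall": float(r),
        "f1": float(f1),
    }


def cross_validate_pipeline(
    dataset: list[GripSequence],
    n_splits: int = 5,
    seed: int = 1234,
    augment: bool = True,
    classifier_config: dict | None = None,
    mode: str = "summary",
) -> dict:
    """Stratified k-fold evaluation of the full pipeline.

    Within each training fold the traditional class is augmented (doubled)
    before summarization, then a :class:`GripClassifier` is fit and scored
    on the untouched test fold.  ``mode="frame_vote"`` selects the
    per-frame-voting variant: the tree consumes per-frame feature rows and
    each test trial takes the majority vote of its frames.

    Returns per-fold metrics plus their means.
    """
    from sklearn.model_selection import StratifiedKFold

    labels = np.array([s.label for s in dataset])
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    summarizer = SequenceSummarizer()
    cache = {id(s): summarize_sequence(s).vector() for s in dataset}

    folds = []
    for k, (tr, te) in enumerate(skf.split(np.zeros(len(dataset)), labels)):
        train_seqs = [dataset[i] for i in tr]
        train_labels = list(labels[tr])
        if augment:
            train_seqs, train_labels = augment_samples(
                train_seqs, train_labels, seed=seed + k
            )
        if mode == "summary":
            X_train = np.vstack(
                [
                    cache[id(s)] if id(s) in cache else summarize_sequence(s).vector()
                    for s in train_seqs
                ]
            )
            clf = GripClassifier(**(classifier_config or {})).fit(
                X_train, np.array(train_labels)
            )
            X_test = np.vstack([cache[id(dataset[i])] for i in te])
            pred = clf.predict(X_test)
        elif mode == "frame_vote":
            Xs, ys = [], []
            for s, lab in zip(train_seqs, train_labels):
                F = _frame_rows(s)
                Xs.append(F)
                ys += [lab] * len(F)
            clf = GripClassifier(**(classifier_config or {})).fit(
                np.vstack(Xs), np.array(ys)
            )
            pred = np.array(
                [_majority(clf.predict(_frame_rows(dataset[i]))) for i in te]
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        folds.append(evaluate_metrics(pred, labels[te]))
    _ = summarizer  # kept for interface symmetry
    means = {m: float(np.mean([f[m] for f in folds])) for m in folds[0]}
    return {"folds": folds, "mean": means, "n_splits": n_splits, "seed": seed}


def _frame_rows(seq: GripSequence) -> np.ndarray:
    cols = feature_matrix(seq)
    return np.column_stack([cols[ch] for ch in CHANNELS])


def _majority(labels: np.ndarray):
    vals, counts = np.unique(labels, return_counts=True)
    return vals[counts.argmax()]
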