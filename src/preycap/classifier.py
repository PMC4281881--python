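"""RBF-SVM bout classification, cross-validation, parameter selection,
prey-capture scoring and tuning curves.

The classifier separates prey-capture bouts from spontaneous swims in the
space of the per-bout kinematic parameters. Folds for cross-validation
are stratified by class and additionally balance the mean of the first
feature across folds (serpentine assignment after sorting by feature
value), which also makes fold assignment a function of the data content
rather than of row order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .core import Bout
from .exceptions import (
    InvalidParameterError,
    SchemaError,
    StratificationError,
)
from .features import FEATURE_NAMES

LABELS = ("prey_capture", "spontaneous")


@dataclass
class LabeledBoutSet:
    """Feature matrix plus labels for training/validation.

    features : DataFrame with one row per bout and the 16 named feature
        columns (missing values allowed only in f6).
    labels : array of 'prey_capture' / 'spontaneous'.
    provenance : optional DataFrame aligned with features (trial/bout ids).
    """

    features: pd.DataFrame
    labels: np.ndarray
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.features) != len(self.labels):
            raise InvalidParameterError("features and labels differ in length")

    def subset(self, names: list[str]) -> pd.DataFrame:
        missing = [n for n in names if n not in self.features.columns]
        if missing:
            raise SchemaError(f"feature columns absent: {missing}")
        return self.features[names]


@dataclass
class CVReport:
    """Cross-validation outcome: pooled and per-fold accuracy, confusion."""

    pooled_accuracy: float
    fold_accuracies: list[float]
    confusion: pd.DataFrame  # rows: true, cols: predicted
    fold_assignments: np.ndarray

    @property
    def mean_fold_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


@dataclass
class ParameterSelectionCurve:
    """Accuracy as a function of parameter count, and the chosen count."""

    candidate_order: list[str]
    accuracy_by_k: dict[int, float]
    selected_k: int

    @property
    def selected_features(self) -> list[str]:
        return self.candidate_order[: self.selected_k]


@dataclass
class TrainedClassifier:
    """A fitted RBF-SVM plus everything needed to reproduce its decisions:
    the feature subset, per-feature centering/scaling from the training
    data, the f6 imputation value, and per-class training counts."""

    feature_subset: list[str]
    center: np.ndarray
    spread: np.ndarray
    svc: SVC
    f6_impute: float
    training_counts: dict[str, int]
    training_accuracy: float
    C: float = 1.0
    gamma: float | str = "scale"

    def _prepare(self, features: pd.DataFrame) -> np.ndarray:
        missing = [n for n in self.feature_subset if n not in features.columns]
        if missing:
            raise SchemaError(f"feature columns absent: {missing}")
        X = features[self.feature_subset].to_numpy(dtype=float).copy()
        if "f6_mean_frames_between_peaks" in self.feature_subset:
            j = self.feature_subset.index("f6_mean_frames_between_peaks")
            col = X[:, j]
            col[~np.isfinite(col)] = self.f6_impute
        if not np.isfinite(X).all():
            raise SchemaError("non-finite feature values outside f6")
        return (X - self.center) / self.spread

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        if len(features) == 0:
            return np.array([], dtype=object)
        return self.svc.predict(self._prepare(features))

    def decision_function(self, features: pd.DataFrame) -> np.ndarray:
        return self.svc.decision_function(self._prepare(features))


def _impute_f6(X: np.ndarray, names: list[str], value: float | None = None) -> tuple[np.ndarray, float]:
    X = X.copy()
    f6_val = 0.0
    if "f6_mean_frames_between_peaks" in names:
        j = names.index("f6_mean_frames_between_peaks")
        col = X[:, j]
        finite = col[np.isfinite(col)]
        f6_val = value if value is not None else (float(np.median(finite)) if finite.size else 0.0)
        col[~np.isfinite(col)] = f6_val
        X[:, j] = col
    return X, f6_val


def stratified_folds(
    X: np.ndarray, y: np.ndarray, folds: int, seed: int = 0
) -> np.ndarray:
    """Fold assignment: stratified by class, balancing the first-feature
    mean across folds via serpentine assignment of value-sorted rows.

    Deterministic and content-keyed: permuting the rows permutes the
    assignment identically, so pooled CV accuracy is order invariant.
    """
    assignment = np.full(len(y), -1, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < folds:
            raise StratificationError(
                f"class {cls!r} has {idx.size} members; needs >= {folds}"
            )
        # sort by first feature, then remaining columns as tie-breakers
        keys = [X[idx, j] for j in range(X.shape[1] - 1, -1, -1)]
        order = idx[np.lexsort(keys)]
        pattern = np.concatenate([np.arange(folds), np.arange(folds)[::-1]])
        assignment[order] = np.resize(pattern, order.size)
    return assignment


def _fit_svc(
    Xtr: np.ndarray, ytr: np.ndarray, C: float, gamma: float | str
) -> tuple[SVC, np.ndarray, np.ndarray]:
    center = Xtr.mean(axis=0)
    spread = Xtr.std(axis=0)
    spread[spread == 0] = 1.0
    svc = SVC(C=C, kernel="rbf", gamma=gamma)
    svc.fit((Xtr - center) / spread, ytr)
    return svc, center, spread


def cross_validate(
    data: LabeledBoutSet,
    feature_subset: list[str] | None = None,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
    gamma: float | str = "scale",
) -> CVReport:
    """Stratified k-fold cross-validation of the RBF-SVM.

    Returns pooled accuracy (all held-out predictions combined) and the
    per-fold accuracies, plus the pooled confusion table.
    """
    names = feature_subset or list(data.features.columns)
    X = data.subset(names).to_numpy(dtype=float)
    y = data.labels
    Ximp, _ = _impute_f6(X, names)
    assignment = stratified_folds(Ximp, y, folds=folds, seed=seed)
    pred = np.empty(len(y), dtype=object)
    fold_acc = []
    for k in range(folds):
        test = assignment == k
        train = ~test
        Xtr, f6val = _impute_f6(X[train], names)
        Xte, _ = _impute_f6(X[test], names, value=f6val)
        svc, center, spread = _fit_svc(Xtr, y[train], C, gamma)
        p = svc.predict((Xte - center) / spread)
        pred[test] = p
        fold_acc.append(float(np.mean(p == y[test])))
    pooled = float(np.mean(pred == y))
    classes = sorted(np.unique(y))
    conf = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(y, pred):
        conf.loc[t, p] += 1
    return CVReport(
        pooled_accuracy=pooled,
        fold_accuracies=fold_acc,
        confusion=conf,
        fold_assignments=assignment,
    )


def rank_features_by_accuracy(
    data: LabeledBoutSet,
    candidates: list[str] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> list[str]:
    """Rank candidate features by their single-feature CV accuracy."""
    candidates = candidates or list(data.features.columns)
    scores = {
        name: cross_validate(data, [name], folds=folds, seed=seed).pooled_accuracy
        for name in candidates
    }
    return sorted(candidates, key=lambda n: (-scores[n], candidates.index(n)))


def select_parameters(
    data: LabeledBoutSet,
    candidate_order: list[str] | None = None,
    folds: int = 5,
    seed: int = 0,
    tolerance: float = 0.005,
) -> ParameterSelectionCurve:
    """Accuracy-vs-parameter-count curve with minimal-k selection.

    Cross-validates on the first k candidates for k = 1..K and selects the
    smallest k whose accuracy is within ``tolerance`` of the maximum.
    """
    order = candidate_order or rank_features_by_accuracy(data, folds=folds, seed=seed)
    if len(order) < 2:
        raise InvalidParameterError("need at least 2 candidate parameters")
    acc = {
        k: cross_validate(data, order[:k], folds=folds, seed=seed).pooled_accuracy
        for k in range(1, len(order) + 1)
    }
    best = max(acc.values())
    selected = min(k for k, a in acc.items() if a >= best - tolerance)
    return ParameterSelectionCurve(
        candidate_order=list(order), accuracy_by_k=acc, selected_k=selected
    )


def train(
    data: LabeledBoutSet,
    feature_subset: list[str] | None = None,
    C: float = 1.0,
    gamma: float | str = "scale",
) -> TrainedClassifier:
    """Fit the RBF-SVM on the full labeled set.

    Features are centered/scaled on training statistics; zero-variance
    features are dropped with a warning; missing f6 values are imputed
    with the training-set median.
    """
    names = list(feature_subset or data.features.columns)
    y = data.labels
    if len(np.unique(y)) < 2:
        raise InvalidParameterError("training requires both classes present")
    X = data.subset(names).to_numpy(dtype=float)
    X, f6val = _impute_f6(X, names)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping zero-variance features: {dropped}")
        names = [n for n, k in zip(names, keep) if k]
        X = X[:, keep]
    svc, center, spread = _fit_svc(X, y, C, gamma)
    pred = svc.predict((X - center) / spread)
    counts = {str(c): int(np.sum(y == c)) for c in np.unique(y)}
    return TrainedClassifier(
        feature_subset=names,
        center=center,
        spread=spread,
        svc=svc,
        f6_impute=f6val,
        training_counts=counts,
        training_accuracy=float(np.mean(pred == y)),
        C=C,
        gamma=gamma,
    )


def classify_bouts(clf: TrainedClassifier, features: pd.DataFrame) -> np.ndarray:
    """Labels for a feature matrix (one per row); empty input → empty output."""
    return clf.predict(features)


def prey_capture_score(
    bouts: list[Bout], trial_frames: int, frame_rate: float | None = None
) -> float:
    """Percentage of trial time spent in prey-capture-labeled bouts."""
    if trial_frames <= 0:
        raise InvalidParameterError("trial_frames must be positive")
    frames = sum(b.n_frames for b in bouts if b.label == "prey_capture")
    return 100.0 * frames / trial_frames


def tuning_curve(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-condition normalized mean ± SEM across larvae.

    ``scores``: rows = larvae, columns = stimulus conditions. Each larva's
    scores are expressed as a percentage of that larva's maximum; larvae
    with all-zero (or all-missing) scores are excluded with a warning.
    Returns a DataFrame indexed by condition with 'mean', 'sem', 'n'.
    """
    rows = []
    kept = []
    for larva, row in scores.iterrows():
        vals = row.to_numpy(dtype=float)
        m = np.nanmax(vals) if np.isfinite(vals).any() else 0.0
        if not m > 0:
            warnings.warn(f"larva {larva!r} has no nonzero score; excluded")
            continue
        rows.append(100.0 * vals / m)
        kept.append(larva)
    if not rows:
        raise InvalidParameterError("no larva has a nonzero score")
    norm = np.vstack(rows)
    n = np.sum(np.isfinite(norm), axis=0)
    mean = np.nanmean(norm, axis=0)
    sem = _nansem(norm, n)
    return pd.DataFrame(
        {"mean": mean, "sem": sem, "n": n}, index=scores.columns
    )


def _nansem(norm: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Column SEM across larvae; 0 where only one larva contributes."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(norm, axis=0, ddof=1)
    return np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
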