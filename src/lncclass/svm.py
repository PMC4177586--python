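"""Binary coding/non-coding classifier: balanced training-set assembly,
0-1 feature scaling, RBF-SVM grid search with stratified cross-validation,
training, prediction with decision values, and model persistence.

Label convention: coding (mRNA) = +1, non-coding (lncRNA) = -1, so a
positive SVM decision value means an mRNA call at the default cutoff of 0.
Ties at exactly the cutoff are classified lncRNA.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .errors import InputError, ModelMismatchError
from .kmers import CalibrationScheme, PatternTable, default_calibration, enumerate_patterns

logger = logging.getLogger(__name__)

LABEL_CODING = "mRNA"
LABEL_NONCODING = "lncRNA"

BUNDLE_FORMAT_VERSION = 1

#: LIBSVM-style default search grid: C = 2^-5, 2^-3, ..., 2^15;
#: gamma = 2^-15, 2^-13, ..., 2^3
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0 ** e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** e for e in range(-15, 4, 2))

#: coarse preset for quick runs
COARSE_C_GRID: tuple[float, ...] = tuple(2.0 ** e for e in (-1, 3, 7, 11))
COARSE_GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** e for e in (-9, -5, -1))


def build_balanced_training_set(pos: np.ndarray, neg: np.ndarray,
                                seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Assemble a balanced labelled matrix by downsampling the larger class.

    The larger class is sampled without replacement (seeded) down to the
    smaller class's size. Returns (X, y) with y in {+1 coding, -1
    non-coding}; positive rows come first.
    """
    pos = np.asarray(pos)
    neg = np.asarray(neg)
    if pos.shape[0] == 0 or neg.shape[0] == 0:
        raise InputError("both classes must be non-empty to build a training set")
    rng = np.random.default_rng(seed)
    n = min(pos.shape[0], neg.shape[0])
    if pos.shape[0] > n:
        pos = pos[np.sort(rng.choice(pos.shape[0], size=n, replace=False))]
    if neg.shape[0] > n:
        neg = neg[np.sort(rng.choice(neg.shape[0], size=n, replace=False))]
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(n, dtype=int), -np.ones(n, dtype=int)])
    return X, y


def fit_scaler(train: np.ndarray) -> MinMaxScaler:
    """Fit a per-feature 0-1 scaler on training data.

    Columns with max == min map to 0. No clipping is applied, so unseen
    values outside the training range transform outside [0, 1], matching
    train/test scaling semantics of SVM front-end tooling.
    """
    train = np.asarray(train)
    if train.shape[0] == 0:
        raise InputError("cannot fit a scaler on an empty matrix")
    return MinMaxScaler(feature_range=(0.0, 1.0), clip=False).fit(train)


def apply_scaler(scaler: MinMaxScaler, matrix: np.ndarray) -> np.ndarray:
    """Apply a fitted scaler; raises on a feature-count mismatch."""
    return scaler.transform(np.asarray(matrix))


@dataclass(frozen=True)
class GridSearchResult:
    """Outcome of an exhaustive (C, gamma) search under stratified CV."""

    best_C: float
    best_gamma: float
    cv_accuracy: float
    grid: tuple[tuple[float, float, float], ...] = field(repr=False)


def grid_search(X: np.ndarray, y: np.ndarray,
                C_grid: Sequence[float] = DEFAULT_C_GRID,
                gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
                folds: int = 10, seed: int = 0) -> GridSearchResult:
    """Exhaustive RBF-SVM parameter search with stratified k-fold CV.

    Folds are stratified and seeded for reproducibility. Ties in CV
    accuracy are broken deterministically: smallest C, then smallest gamma.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise InputError("grid search needs exactly two classes")
    if counts.min() < folds:
        raise InputError(
            f"need at least {folds} examples per class for {folds}-fold CV "
            f"(smallest class has {counts.min()})")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    grid: list[tuple[float, float, float]] = []
    for C in C_grid:
        for gamma in gamma_grid:
            acc = cross_val_score(SVC(kernel="rbf", C=C, gamma=gamma),
                                  X, y, cv=cv, scoring="accuracy").mean()
            grid.append((float(C), float(gamma), float(acc)))
    best = min(grid, key=lambda t: (-t[2], t[0], t[1]))
    return GridSearchResult(best_C=best[0], best_gamma=best[1],
                            cv_accuracy=best[2], grid=tuple(grid))


@dataclass
class ClassifierBundle:
    """A fitted scaler + RBF-SVM plus the feature-space metadata needed to
    apply it safely: the k range and pattern ordering, calibration scheme,
    and training provenance. Round-trips through :func:`save_bundle` /
    :func:`load_bundle` with identical predictions."""

    scaler: MinMaxScaler
    svm: SVC
    k_min: int
    k_max: int
    calibration: CalibrationScheme
    metadata: dict = field(default_factory=dict)
    format_version: int = BUNDLE_FORMAT_VERSION

    @property
    def n_features(self) -> int:
        return int(self.svm.n_features_in_)

    def pattern_table(self) -> PatternTable:
        return enumerate_patterns(self.k_min, self.k_max)


@dataclass(frozen=True)
class Prediction:
    """One transcript's call: signed decision value and derived label.

    Greater absolute decision values indicate greater confidence; no
    probability calibration is applied.
    """

    transcript_id: str
    decision_value: float
    label: str
    cutoff: float


def train(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
          k_min: int = 1, k_max: int = 5,
          calibration: CalibrationScheme | None = None,
          metadata: dict | None = None) -> ClassifierBundle:
    """Fit the 0-1 scaler and RBF-SVM on a labelled (+1/-1) matrix."""
    X = np.asarray(X)
    y = np.asarray(y)
    if np.unique(y).size != 2:
        raise InputError("training requires both classes present")
    scaler = fit_scaler(X)
    svm = SVC(kernel="rbf", C=C, gamma=gamma)
    svm.fit(scaler.transform(X), y)
    if calibration is None:
        calibration = default_calibration(k_min, k_max)
    meta = {"C": C, "gamma": gamma,
            "n_train_pos": int((y == 1).sum()),
            "n_train_neg": int((y == -1).sum())}
    meta.update(metadata or {})
    return ClassifierBundle(scaler=scaler, svm=svm, k_min=k_min, k_max=k_max,
                            calibration=calibration, metadata=meta)


def decision_values(bundle: ClassifierBundle, features: np.ndarray) -> np.ndarray:
    """Signed decision-function values; positive means coding-like."""
    features = np.asarray(features)
    if features.ndim != 2 or features.shape[1] != bundle.n_features:
        raise ModelMismatchError(
            f"feature matrix has {features.shape[-1] if features.ndim else 0} "
            f"columns but the model expects {bundle.n_features}")
    d = bundle.svm.decision_function(apply_scaler(bundle.scaler, features))
    # sklearn orients the decision function toward classes_[1]; with labels
    # {-1, +1} that is +1 (coding), so positive d already means mRNA
    return np.asarray(d, dtype=float)


def predict(bundle: ClassifierBundle, features: np.ndarray,
            ids: Sequence[str] | None = None,
            cutoff: float = 0.0) -> list[Prediction]:
    """Label transcripts: mRNA iff decision value > cutoff, else lncRNA."""
    d = decision_values(bundle, features)
    if ids is None:
        ids = [f"record_{i}" for i in range(len(d))]
    if len(ids) != len(d):
        raise InputError("ids and feature rows differ in length")
    return [
        Prediction(transcript_id=tid, decision_value=float(di),
                   label=LABEL_CODING if di > cutoff else LABEL_NONCODING,
                   cutoff=cutoff)
        for tid, di in zip(ids, d)
    ]


def save_bundle(bundle: ClassifierBundle, path: str | Path) -> None:
    """Persist a model archive plus a human-readable JSON sidecar."""
    path = Path(path)
    payload = {
        "format_version": bundle.format_version,
        "scaler": bundle.scaler,
        "svm": bundle.svm,
        "k_min": bundle.k_min,
        "k_max": bundle.k_max,
        "calibration_name": bundle.calibration.name,
        "calibration_weights": {str(k): v for k, v in bundle.calibration.weights.items()},
        "metadata": bundle.metadata,
    }
    joblib.dump(payload, path)
    sidecar = {
        "format_version": bundle.format_version,
        "k_min": bundle.k_min,
        "k_max": bundle.k_max,
        "n_features": bundle.n_features,
        "calibration": bundle.calibration.name,
        "metadata": bundle.metadata,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_bundle(path: str | Path) -> ClassifierBundle:
    path = Path(path)
    if not path.exists():
        raise InputError(f"model archive not found: {path}")
    payload = joblib.load(path)
    if payload.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise ModelMismatchError(
            f"unsupported model format version {payload.get('format_version')}")
    calibration = CalibrationScheme(
        weights={int(k): float(v) for k, v in payload["calibration_weights"].items()},
        name=payload["calibration_name"])
    return ClassifierBundle(scaler=payload["scaler"], svm=payload["svm"],
                            k_min=payload["k_min"], k_max=payload["k_max"],
                            calibration=calibration,
                            metadata=payload["metadata"])


def train_classifier(pos: np.ndarray, neg: np.ndarray, seed: int = 0,
                     C_grid: Sequence[float] = DEFAULT_C_GRID,
                     gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
                     folds: int = 10, k_min: int = 1, k_max: int = 5,
                     calibration: CalibrationScheme | None = None,
                     ) -> tuple[ClassifierBundle, GridSearchResult]:
    """End-to-end training: balance classes, scale, grid-search, final fit.

    The grid search scales features with a scaler fitted on the balanced
    training matrix (mirroring a scale-then-search workflow); the returned
    bundle refits scaler and SVM on the same data at the best (C, gamma).
    """
    X, y = build_balanced_training_set(pos, neg, seed)
    scaler = fit_scaler(X)
    result = grid_search(apply_scaler(scaler, X), y, C_grid=C_grid,
                         gamma_grid=gamma_grid, folds=folds, seed=seed)
    bundle = train(X, y, C=result.best_C, gamma=result.best_gamma,
                   k_min=k_min, k_max=k_max, calibration=calibration,
                   metadata={"seed": seed, "cv_accuracy": result.cv_accuracy})
    return bundle, result
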