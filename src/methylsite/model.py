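"""RBF-kernel SVM training, tuning, and prediction on 346-D feature vectors.

The classifier is a maximum-margin SVM with the radial basis kernel, fitted
at parameters (c, gamma) selected by grid search over the conventional
coarse log2 grid.  Class labels are +1 (methylation site) and -1
(non-methylation site); the decision threshold is 0, with a decision value
of exactly 0 called positive.  Features are rescaled per dimension to
[0, 1] using training-set minima/maxima before fitting; the scaling
parameters travel with the model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.svm import SVC

from .encoder import SCHEMA_VERSION


class ModelError(ValueError):
    pass


class DegenerateTrainingError(ModelError):
    """Training data contains a single class."""


@dataclass
class TrainingConfig:
    """SVM hyper-parameters and tuning protocol.

    The default grid is the conventional coarse search grid of the reference
    SVM library: log2 c in {-5, -3, ..., 15} and log2 gamma in
    {-15, -13, ..., 3}.
    """

    c: float = 1.0
    gamma: float = 1.0 / 346.0
    grid_log2c: tuple = tuple(range(-5, 17, 2))
    grid_log2gamma: tuple = tuple(range(-15, 5, 2))
    cv_protocol: str = "k-fold"  # "k-fold" or "jackknife"
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c <= 0 or self.gamma <= 0:
            raise ModelError("c and gamma must be positive")
        if not self.grid_log2c or not self.grid_log2gamma:
            raise ModelError("parameter grids must be non-empty")
        if self.cv_protocol not in ("k-fold", "jackknife"):
            raise ModelError(f"unknown cv_protocol {self.cv_protocol!r}")


@dataclass
class TrainedModel:
    """A fitted RBF-SVM plus the scaling and schema needed to apply it."""

    svc: SVC
    c: float
    gamma: float
    scale_min: np.ndarray
    scale_range: np.ndarray
    schema_version: str
    fingerprint: str


def _validate_labels(y: np.ndarray) -> None:
    values = set(np.unique(y).tolist())
    if not values <= {-1, 1}:
        raise ModelError(f"labels must be in {{-1, +1}}, got {sorted(values)}")
    if len(values) < 2:
        raise DegenerateTrainingError("training data contains a single class")


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng[rng == 0.0] = 1.0  # constant feature -> maps to 0
    return lo, rng


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    c: float,
    gamma: float,
    schema_version: str = SCHEMA_VERSION,
) -> TrainedModel:
    """Fit the RBF-SVM at (c, gamma); deterministic for fixed inputs."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.size:
        raise ModelError("features and labels have different lengths")
    _validate_labels(y)
    lo, rng = _fit_scaler(X)
    svc = SVC(C=c, kernel="rbf", gamma=gamma)
    svc.fit((X - lo) / rng, y)
    fingerprint = hashlib.sha256(X.tobytes() + y.tobytes()).hexdigest()[:16]
    return TrainedModel(
        svc=svc,
        c=c,
        gamma=gamma,
        scale_min=lo,
        scale_range=rng,
        schema_version=schema_version,
        fingerprint=fingerprint,
    )


def labels_from_decision(decision: np.ndarray) -> np.ndarray:
    """Apply the zero threshold: decision value >= 0 is called positive."""
    return np.where(np.asarray(decision, dtype=float) >= 0.0, 1, -1)


def decision_values(
    model: TrainedModel, X: np.ndarray, schema_version: str = SCHEMA_VERSION
) -> np.ndarray:
    if schema_version != model.schema_version:
        raise ModelError(
            f"feature schema {schema_version!r} does not match the model's "
            f"{model.schema_version!r}"
        )
    X = np.asarray(X, dtype=float)
    return model.svc.decision_function((X - model.scale_min) / model.scale_range)


def predict_labels(
    model: TrainedModel, X: np.ndarray, schema_version: str = SCHEMA_VERSION
) -> tuple[np.ndarray, np.ndarray]:
    """Return (+/-1 labels, decision values) for a feature matrix."""
    d = decision_values(model, X, schema_version)
    return labels_from_decision(d), d


@dataclass
class GridSearchResult:
    best_c: float
    best_gamma: float
    scores: dict  # (c, gamma) -> mean CV accuracy


def grid_search(
    X: np.ndarray, y: np.ndarray, config: TrainingConfig
) -> GridSearchResult:
    """Exhaustive (c, gamma) search under the configured cross-validation.

    Returns the cell with the highest mean accuracy; ties are broken by
    smaller c, then smaller gamma.  The same folds are reused for every cell.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _validate_labels(y)
    if config.cv_protocol == "jackknife":
        splits = list(LeaveOneOut().split(X))
    else:
        cv = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed
        )
        splits = list(cv.split(X, y))
    scores: dict[tuple[float, float], float] = {}
    best = None
    for log2c in sorted(config.grid_log2c):
        for log2g in sorted(config.grid_log2gamma):
            c, gamma = 2.0 ** log2c, 2.0 ** log2g
            correct = total = 0
            for train_idx, test_idx in splits:
                m = train_svm(X[train_idx], y[train_idx], c, gamma)
                pred, _ = predict_labels(m, X[test_idx])
                correct += int(np.sum(pred == y[test_idx]))
                total += test_idx.size
            acc = correct / total
            scores[(c, gamma)] = acc
            if best is None or acc > best[0]:
                best = (acc, c, gamma)
    assert best is not None
    return GridSearchResult(best_c=best[1], best_gamma=best[2], scores=scores)


def save_model(model: TrainedModel, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise ModelError(f"{path} does not contain a trained model")
    return model
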