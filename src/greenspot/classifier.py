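"""RBF-SVM training, grid search and evaluation on shape-feature vectors.

The kernel is K(xi, x) = exp(-gamma ||xi - x||^2) with gamma = 1/(2 sigma^2).
Hyperparameters are tuned by exhaustive grid search over integer powers of
two, C in 2^-15..2^15 and sigma in 2^-10..2^10, scored by stratified N-fold
cross-validated accuracy (N = 5 by default, reduced when the sample budget
rule n/N > 3d demands it). Multi-class decisions use one-vs-one voting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .shape_features import FeatureScaler, ShapeFeatures

__all__ = [
    "CvConfig",
    "SvmModel",
    "Metrics",
    "rbf_kernel",
    "gamma_from_sigma",
    "select_fold_count",
    "grid_search_train",
    "predict",
    "evaluate",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


def gamma_from_sigma(sigma: float) -> float:
    """Kernel width sigma -> gamma = 1/(2 sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return 1.0 / (2.0 * sigma**2)


def rbf_kernel(xi: np.ndarray, x: np.ndarray, gamma: float) -> float:
    """Gaussian kernel exp(-gamma ||xi - x||^2), in (0, 1]."""
    xi = np.asarray(xi, dtype=float)
    x = np.asarray(x, dtype=float)
    if xi.shape != x.shape:
        raise ValueError(f"shape mismatch: {xi.shape} vs {x.shape}")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return float(np.exp(-gamma * np.sum((xi - x) ** 2)))


def select_fold_count(n: int, d: int, default: int = 5) -> int:
    """Fold count: the default N when n/N > 3d holds, else the largest N <= default that does."""
    if n <= 0 or d <= 0:
        raise ValueError("n and d must be positive")
    for N in range(default, 1, -1):
        if n / N > 3 * d:
            return N
    raise ValueError(f"too few samples: n={n} cannot satisfy n/2 > 3d with d={d}")


@dataclass
class CvConfig:
    """Grid-search / cross-validation settings."""

    n_folds: int = 5
    c_exponents: tuple[int, int] = (-15, 15)       # C = 2^e, inclusive range
    sigma_exponents: tuple[int, int] = (-10, 10)   # sigma = 2^e, inclusive

    def grid(self) -> list[tuple[int, int]]:
        return [(ce, se)
                for ce in range(self.c_exponents[0], self.c_exponents[1] + 1)
                for se in range(self.sigma_exponents[0], self.sigma_exponents[1] + 1)]


@dataclass
class SvmModel:
    C: float
    sigma: float
    classes: list[str]
    svc: SVC
    scaler: FeatureScaler | None = None
    cv_report: pd.DataFrame | None = field(default=None, repr=False)
    # retained so the model can be re-fit deterministically after persistence
    train_X: np.ndarray | None = field(default=None, repr=False)
    train_y: np.ndarray | None = field(default=None, repr=False)

    @property
    def gamma(self) -> float:
        return gamma_from_sigma(self.sigma)


def _make_svc(C: float, sigma: float) -> SVC:
    return SVC(C=C, kernel="rbf", gamma=gamma_from_sigma(sigma),
               decision_function_shape="ovo")


def grid_search_train(X: np.ndarray, y, cfg: CvConfig | None = None,
                      seed: int = 0, scaler: FeatureScaler | None = None,
                      ) -> SvmModel:
    """Exhaustive (C, sigma) grid search with stratified N-fold CV.

    Fold assignment is deterministic given ``seed`` and shared across the
    whole grid. The returned model is re-fit on all data at the grid point
    with the highest mean CV accuracy; ties break toward smaller C, then
    larger sigma.
    """
    cfg = cfg or CvConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")

    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    rows = []
    for ce, se in cfg.grid():
        C, sigma = 2.0**ce, 2.0**se
        correct = 0
        for train_idx, test_idx in folds:
            svc = _make_svc(C, sigma)
            svc.fit(X[train_idx], y[train_idx])
            correct += int((svc.predict(X[test_idx]) == y[test_idx]).sum())
        rows.append((ce, se, correct / len(y)))
    report = pd.DataFrame(rows, columns=["C_exp", "sigma_exp", "mean_cv_accuracy"])

    # max accuracy; ties -> smaller C then larger sigma
    best = max(rows, key=lambda r: (r[2], -r[0], r[1]))
    C, sigma = 2.0 ** best[0], 2.0 ** best[1]
    svc = _make_svc(C, sigma)
    svc.fit(X, y)
    return SvmModel(C=C, sigma=sigma, classes=[str(c) for c in classes],
                    svc=svc, scaler=scaler, cv_report=report,
                    train_X=X.copy(), train_y=y.copy())


def predict(model: SvmModel, features) -> np.ndarray:
    """Predict labels for ShapeFeatures, a list of them, or raw vectors.

    Applies the attached scaler when the input is unscaled features.
    """
    if model.svc is None or not hasattr(model.svc, "support_"):
        raise ValueError("model is not trained")
    if isinstance(features, ShapeFeatures):
        features = [features]
    if isinstance(features, list) and features and isinstance(features[0], ShapeFeatures):
        if model.scaler is None:
            raise ValueError("model has no scaler attached for raw features")
        X = model.scaler.transform(features)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
    return model.svc.predict(X)


@dataclass
class Metrics:
    """Binary confusion counts against a positive class, plus derived rates."""

    tp: int
    fp: int
    tn: int
    fn: int
    per_class_accuracy: dict[str, float]

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total * 100.0

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom * 100.0 if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom * 100.0 if denom else 0.0


def evaluate(predicted, truth, positive_class: str) -> Metrics:
    """Confusion counts and accuracy/precision/recall (percent) vs. a positive class.

    Also reports per-class row accuracy: correct / total within each true class.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if len(predicted) == 0:
        raise ValueError("empty input")
    if len(predicted) != len(truth):
        raise ValueError("length mismatch")
    pos_pred = predicted == positive_class
    pos_true = truth == positive_class
    tp = int(np.sum(pos_pred & pos_true))
    fp = int(np.sum(pos_pred & ~pos_true))
    fn = int(np.sum(~pos_pred & pos_true))
    tn = int(np.sum(~pos_pred & ~pos_true))
    per_class = {}
    for cls in sorted(set(truth.tolist())):
        sel = truth == cls
        per_class[str(cls)] = float(np.sum(predicted[sel] == cls) / np.sum(sel) * 100.0)
    return Metrics(tp=tp, fp=fp, tn=tn, fn=fn, per_class_accuracy=per_class)


def save_model(model: SvmModel, path: str | Path) -> None:
    """Persist as versioned JSON: scaler, (C, sigma), labels and training set.

    Loading re-fits the SVM on the stored (scaled) training data, which is
    deterministic, so save/load round-trips reproduce identical predictions.
    """
    if model.train_X is None:
        raise ValueError("model lacks training data; cannot persist")
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "C": model.C,
        "sigma": model.sigma,
        "classes": model.classes,
        "scaler": None if model.scaler is None else {
            "mins": model.scaler.mins.tolist(),
            "maxs": model.scaler.maxs.tolist(),
        },
        "train_X": model.train_X.tolist(),
        "train_y": [str(v) for v in model.train_y.tolist()],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> SvmModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    X = np.asarray(payload["train_X"], dtype=float)
    y = np.asarray(payload["train_y"])
    svc = _make_svc(payload["C"], payload["sigma"])
    svc.fit(X, y)
    scaler = None
    if payload["scaler"] is not None:
        scaler = FeatureScaler(mins=np.asarray(payload["scaler"]["mins"]),
                               maxs=np.asarray(payload["scaler"]["maxs"]))
    return SvmModel(C=payload["C"], sigma=payload["sigma"],
                    classes=payload["classes"], svc=svc, scaler=scaler,
                    train_X=X, train_y=y)
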