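"""The three benchmark classifiers: naive Bayes, k-nearest neighbors,
logistic regression.

Features are the 30 item scores — integers from a full questionnaire or
reals from CAT expected-value imputation — fed in raw (no standardisation).
Naive Bayes is Gaussian per feature (the only variant compatible with
real-valued imputed features); KNN uses Euclidean distance and, when
scoring the training set itself, does not exclude the self row; logistic
regression is unregularised maximum likelihood.  Fitting is delegated to
scikit-learn behind this module's surface.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "KINDS",
    "TrainedModel",
    "train",
    "predict_proba",
    "classify",
    "odds",
    "save_model",
    "load_model",
]

KINDS = ("nb", "knn", "lr")

DEFAULT_KNN_K = 1
LR_MAX_ITER = 100


@dataclass
class TrainedModel:
    """A fitted classifier plus the settings needed to reproduce it."""

    kind: str
    estimator: object
    n_features: int
    config: dict = field(default_factory=dict)


def _make_estimator(kind: str, n_rows: int, knn_k: int, lr_max_iter: int):
    if kind == "nb":
        return GaussianNB(var_smoothing=1e-9)
    if kind == "knn":
        if not 1 <= knn_k <= n_rows:
            raise ValueError(f"knn_k must be in 1..{n_rows}, got {knn_k}")
        return KNeighborsClassifier(n_neighbors=knn_k, metric="euclidean")
    if kind == "lr":
        # newton-cholesky is the IRLS-style solver for binary logistic fits;
        # C=inf turns regularisation off
        return LogisticRegression(
            C=np.inf, solver="newton-cholesky", max_iter=lr_max_iter, tol=1e-8
        )
    raise ValueError(f"unknown model kind {kind!r}; expected one of {KINDS}")


def train(
    kind: str,
    features: np.ndarray,
    labels: np.ndarray,
    knn_k: int = DEFAULT_KNN_K,
    lr_max_iter: int = LR_MAX_ITER,
) -> TrainedModel:
    """Fit one of the three model kinds on a complete feature matrix."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=np.int64)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("features must be 2-D with one row per label")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    est = _make_estimator(kind, X.shape[0], knn_k, lr_max_iter)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        est.fit(X, y)
    for w in caught:
        if not issubclass(w.category, ConvergenceWarning):
            continue
        warnings.warn(
            f"{kind} fit did not fully converge; using last iterate ({w.message})",
            RuntimeWarning,
            stacklevel=2,
        )
    cfg = {"knn_k": knn_k} if kind == "knn" else ({"max_iter": lr_max_iter} if kind == "lr" else {})
    return TrainedModel(kind=kind, estimator=est, n_features=X.shape[1], config=cfg)


def predict_proba(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """P(label = 1) per row."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature count mismatch: model expects {model.n_features}, got {X.shape[1]}"
        )
    proba = model.estimator.predict_proba(X)
    pos_col = int(np.flatnonzero(model.estimator.classes_ == 1)[0])
    return proba[:, pos_col]


def classify(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Label 1 iff probability >= threshold (boundary inclusive)."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return (p >= threshold).astype(np.int64)


def odds(p: float) -> float:
    """Odds of an event: p / (1 - p); defined for 0 <= p < 1."""
    if not 0.0 <= p < 1.0:
        raise ValueError("odds defined for probabilities in [0, 1)")
    return p / (1.0 - p)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialise a trained model to JSON (knn embeds its training data)."""
    est = model.estimator
    doc: dict = {"kind": model.kind, "n_features": model.n_features, "config": model.config}
    if model.kind == "nb":
        doc["parameters"] = {
            "classes": est.classes_.tolist(),
            "priors": est.class_prior_.tolist(),
            "class_count": est.class_count_.tolist(),
            "theta": est.theta_.tolist(),
            "var": est.var_.tolist(),
        }
    elif model.kind == "lr":
        doc["parameters"] = {
            "classes": est.classes_.tolist(),
            "coef": est.coef_.tolist(),
            "intercept": est.intercept_.tolist(),
        }
    elif model.kind == "knn":
        doc["parameters"] = {
            "X": np.asarray(est._fit_X).tolist(),
            "y": est.classes_[est._y].tolist(),
        }
    else:  # pragma: no cover
        raise ValueError(f"unknown kind {model.kind!r}")
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str | Path) -> TrainedModel:
    """Reconstruct a model saved by :func:`save_model`."""
    with open(path) as fh:
        doc = json.load(fh)
    kind, params = doc["kind"], doc["parameters"]
    if kind == "nb":
        est = GaussianNB()
        est.classes_ = np.asarray(params["classes"])
        est.class_prior_ = np.asarray(params["priors"])
        est.class_count_ = np.asarray(params["class_count"])
        est.theta_ = np.asarray(params["theta"])
        est.var_ = np.asarray(params["var"])
        est.n_features_in_ = doc["n_features"]
    elif kind == "lr":
        est = LogisticRegression(C=np.inf, solver="newton-cholesky", tol=1e-8)
        est.classes_ = np.asarray(params["classes"])
        est.coef_ = np.asarray(params["coef"])
        est.intercept_ = np.asarray(params["intercept"])
        est.n_features_in_ = doc["n_features"]
    elif kind == "knn":
        X = np.asarray(params["X"], dtype=float)
        y = np.asarray(params["y"], dtype=np.int64)
        est = KNeighborsClassifier(
            n_neighbors=doc["config"].get("knn_k", DEFAULT_KNN_K), metric="euclidean"
        )
        est.fit(X, y)
    else:
        raise ValueError(f"unknown kind {kind!r} in {path}")
    return TrainedModel(
        kind=kind, estimator=est, n_features=doc["n_features"], config=doc.get("config", {})
    )
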