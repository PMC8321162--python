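"""Benign/malignant nucleus classification.

Three classical algorithms are supported — an RBF-kernel support vector
machine, k-nearest neighbours and AdaBoost over depth-1 stumps — all run on
z-scored key-parameter vectors. :class:`NucleusClassifier` is a
scikit-learn estimator (fit/predict/get_params) so it composes with
pipelines and model selection; the module-level functions are thin
wrappers for the pipeline code.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve as sk_roc_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .errors import DegenerateTrainingError, SchemaError, UndefinedROCError
from .selection import DEFAULT_KEY_FEATURES

ALGORITHMS = ("svm", "knn", "adaboost")

MALIGNANT = "malignant"
BENIGN = "benign"


@dataclass
class TrainingMetrics:
    """Metrics computed on the training set at fit time."""

    accuracy: float
    tpr: float
    fpr: np.ndarray
    tpr_curve: np.ndarray
    auc: float


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """Threshold-sweep ROC and its trapezoidal AUC.

    ``labels`` may be any two-class labelling; the positive class is
    'malignant' if present, otherwise the lexicographically larger label.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(labels)
    if classes.size < 2:
        raise UndefinedROCError("ROC needs both classes present")
    if classes.size > 2:
        raise UndefinedROCError("ROC is defined for binary labels only")
    pos = MALIGNANT if MALIGNANT in classes else classes[-1]
    fpr, tpr, _ = sk_roc_curve(labels == pos, scores)
    return fpr, tpr, float(sk_auc(fpr, tpr))


def _base_estimator(algorithm: str, seed: int, params: dict):
    if algorithm == "svm":
        return SVC(
            kernel=params.get("kernel", "rbf"),
            C=params.get("C", 1.0),
            gamma=params.get("gamma", "scale"),
            random_state=seed,
        )
    if algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=params.get("k", 5))
    if algorithm == "adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=params.get("n_estimators", 100),
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


class NucleusClassifier(BaseEstimator, ClassifierMixin):
    """Benign/malignant nucleus classifier on key-parameter vectors.

    Parameters
    ----------
    algorithm
        One of ``"svm"``, ``"knn"``, ``"adaboost"``.
    feature_manifest
        Ordered feature names selected from input DataFrames. ``None``
        means: use every numeric column at fit time (metadata columns
        excluded). The string ``"default"`` selects the shipped 22-feature
        key-parameter set.
    seed
        Random state for the underlying learner.
    hyperparams
        Algorithm-specific overrides (``C``, ``gamma``, ``k``,
        ``n_estimators``).
    """

    _META = {"patch_id", "nucleus_label", "tc_label"}

    def __init__(
        self,
        algorithm: str = "svm",
        feature_manifest: list[str] | str | None = None,
        seed: int = 0,
        hyperparams: dict | None = None,
    ):
        self.algorithm = algorithm
        self.feature_manifest = feature_manifest
        self.seed = seed
        self.hyperparams = hyperparams

    # -- helpers ---------------------------------------------------------
    def _resolve_manifest(self, X) -> list[str] | None:
        if self.feature_manifest == "default":
            return list(DEFAULT_KEY_FEATURES)
        if self.feature_manifest is not None:
            return list(self.feature_manifest)
        if isinstance(X, pd.DataFrame):
            return [
                c
                for c in X.columns
                if c not in self._META and pd.api.types.is_numeric_dtype(X[c])
            ]
        return None  # plain array input

    def _matrix(self, X, manifest: list[str] | None) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if manifest is None:
                raise SchemaError("fitted without a manifest but given a DataFrame")
            missing = [c for c in manifest if c not in X.columns]
            if missing:
                raise SchemaError(f"table is missing manifest columns: {missing}")
            return X[manifest].to_numpy(dtype=float)
        arr = np.asarray(X, dtype=float)
        if manifest is not None and arr.shape[1] != len(manifest):
            raise SchemaError(
                f"expected {len(manifest)} feature columns, got {arr.shape[1]}"
            )
        return arr

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y):
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise DegenerateTrainingError(
                f"training labels contain a single class {classes!r}"
            )
        manifest = self._resolve_manifest(X)
        mat = self._matrix(X, manifest)
        pipe = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "model",
                    _base_estimator(self.algorithm, self.seed, self.hyperparams or {}),
                ),
            ]
        )
        pipe.fit(mat, y)
        self.pipeline_ = pipe
        self.classes_ = pipe.named_steps["model"].classes_
        self.feature_manifest_ = manifest
        self.positive_class_ = (
            MALIGNANT if MALIGNANT in self.classes_ else self.classes_[-1]
        )

        pred = pipe.predict(mat)
        scores = self._scores_from_matrix(mat)
        pos = y == self.positive_class_
        fpr, tpr_curve, auc_val = roc_curve(scores, y)
        self.training_metrics_ = TrainingMetrics(
            accuracy=float((pred == y).mean()),
            tpr=float((pred[pos] == self.positive_class_).mean()) if pos.any() else 0.0,
            fpr=fpr,
            tpr_curve=tpr_curve,
            auc=auc_val,
        )
        return self

    def _scores_from_matrix(self, mat: np.ndarray) -> np.ndarray:
        model = self.pipeline_.named_steps["model"]
        scaled = self.pipeline_.named_steps["scale"].transform(mat)
        if hasattr(model, "decision_function"):
            raw = model.decision_function(scaled)
            # decision_function is monotone towards classes_[-1]
            return raw if self.positive_class_ == self.classes_[-1] else -raw
        proba = model.predict_proba(scaled)
        idx = int(np.nonzero(self.classes_ == self.positive_class_)[0][0])
        return proba[:, idx]

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        mat = self._matrix(X, self.feature_manifest_)
        if mat.shape[0] == 0:
            return np.asarray([], dtype=self.classes_.dtype)
        return self.pipeline_.predict(mat)

    def decision_scores(self, X) -> np.ndarray:
        """Monotone malignancy score per row (higher = more malignant)."""
        check_is_fitted(self, "pipeline_")
        mat = self._matrix(X, self.feature_manifest_)
        if mat.shape[0] == 0:
            return np.asarray([], dtype=float)
        return self._scores_from_matrix(mat)

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "pipeline_")
        joblib.dump({"format_version": 1, "model": self}, path)

    @classmethod
    def load(cls, path: str | Path) -> "NucleusClassifier":
        payload = joblib.load(path)
        model = payload["model"]
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a NucleusClassifier")
        return model


def train_classifier(
    table: pd.DataFrame,
    labels,
    algorithm: str = "svm",
    seed: int = 0,
    feature_manifest: list[str] | str | None = None,
    hyperparams: dict | None = None,
) -> NucleusClassifier:
    """Fit a :class:`NucleusClassifier` on a feature table."""
    clf = NucleusClassifier(
        algorithm=algorithm,
        feature_manifest=feature_manifest,
        seed=seed,
        hyperparams=hyperparams,
    )
    return clf.fit(table, labels)


def predict_nuclei(
    model: NucleusClassifier, table: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row class and malignancy score; empty table yields empty arrays."""
    return model.predict(table), model.decision_scores(table)
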