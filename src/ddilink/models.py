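"""Pair classifiers: unsupervised combined similarity and tuned supervised learners.

The unsupervised route averages the z-scored similarity features of each
pair into a single combined score and predicts a link when the score
exceeds a percentile threshold (90th by default, nearest-rank, strict
``>``).  The supervised route wraps five scikit-learn families —
classification tree, k-nearest neighbors, linear-kernel SVM, random
forest, gradient boosting — behind one estimator with cross-validated
hyperparameter selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .semantics import SEMANTIC_FEATURES
from .topology import TOPO_FEATURES

__all__ = [
    "FEATURE_COLUMNS",
    "CLASSIFIER_FAMILIES",
    "CombinedSimilarityClassifier",
    "TunedPairClassifier",
    "ImportanceReport",
    "feature_importance",
    "fit_combined",
    "predict_combined",
    "train_classifier",
    "predict_classifier",
]

#: canonical feature order: eight topological then four semantic columns
FEATURE_COLUMNS = list(TOPO_FEATURES) + list(SEMANTIC_FEATURES)

CLASSIFIER_FAMILIES = ("tree", "knn", "svm_linear", "random_forest", "gbm")


def _as_matrix(X, expected_columns=None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if expected_columns is not None:
            if list(X.columns) != list(expected_columns):
                if set(X.columns) == set(expected_columns):
                    X = X[list(expected_columns)]  # same columns, reordered
                else:
                    raise ValueError(
                        f"feature columns {list(X.columns)} do not match "
                        f"the fitted columns {list(expected_columns)}")
        return X.to_numpy(dtype=float)
    arr = np.asarray(X, dtype=float)
    if expected_columns is not None and arr.shape[1] != len(expected_columns):
        raise ValueError(
            f"expected {len(expected_columns)} feature columns, got {arr.shape[1]}")
    return arr


def extract_features(table: pd.DataFrame,
                     columns: list[str] | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Split a featurized labeled pair table into (X, y)."""
    cols = columns if columns is not None else [
        c for c in FEATURE_COLUMNS if c in table.columns]
    return table[cols], table["label"].to_numpy(dtype=int)


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th smallest value."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("empty value array")
    rank = max(1, math.ceil(percentile / 100.0 * n))
    return float(v[min(rank, n) - 1])


class CombinedSimilarityClassifier:
    """Unsupervised link predictor from the average of z-scored features.

    ``fit`` learns per-feature means/standard deviations on the reference
    rows and a threshold at the given percentile of their combined scores
    (features with zero spread contribute 0 to every score).  ``predict``
    labels a pair 1 when its combined score strictly exceeds the threshold.
    The class label is never used in fitting.

    Parameters
    ----------
    percentile : float in (0, 100)
        Threshold percentile of the combined score, default 90.
    refit_threshold : bool
        When True the threshold is recomputed on each scored set
        (classical mode, train and test thresholds move together); when
        False (default) the fitted threshold is frozen.
    """

    def __init__(self, percentile: float = 90.0, refit_threshold: bool = False):
        self.percentile = percentile
        self.refit_threshold = refit_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {"percentile": self.percentile,
                "refit_threshold": self.refit_threshold}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None) -> "CombinedSimilarityClassifier":
        if not 0.0 < self.percentile < 100.0:
            raise ValueError(f"percentile must be in (0, 100), got {self.percentile}")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
        else:
            self.feature_names_in_ = None
        mat = _as_matrix(X)
        if mat.shape[0] < 2:
            raise ValueError("need at least 2 rows to standardize")
        self.mean_ = mat.mean(axis=0)
        self.scale_ = mat.std(axis=0)
        scores = self._scores(mat)
        self.threshold_ = nearest_rank_percentile(scores, self.percentile)
        self.n_features_in_ = mat.shape[1]
        return self

    def _scores(self, mat: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (mat - self.mean_) / self.scale_
        z[:, self.scale_ == 0] = 0.0
        return z.mean(axis=1)

    def decision_function(self, X) -> np.ndarray:
        """Combined score (mean of z-scored features) per row."""
        mat = _as_matrix(X, self.feature_names_in_)
        if mat.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} columns, got {mat.shape[1]}")
        return self._scores(mat)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        threshold = (nearest_rank_percentile(scores, self.percentile)
                     if self.refit_threshold else self.threshold_)
        return (scores > threshold).astype(int)


# hyperparameter grids mirroring common R defaults for the five families;
# keys are parameter paths inside the per-family pipeline
_DEFAULT_GRIDS = {
    "tree": {"model__max_depth": [2, 4, 8, 16, None]},
    "knn": {"model__n_neighbors": list(range(1, 26, 2))},
    "svm_linear": {"model__estimator__C": [0.01, 0.1, 1.0, 10.0]},
    "random_forest": {},
    "gbm": {},
}


def _build_pipeline(family: str, seed: int) -> Pipeline:
    if family == "tree":
        model = DecisionTreeClassifier(random_state=seed)
        steps = [("model", model)]
    elif family == "knn":
        # distance-based: standardize features first
        steps = [("scale", StandardScaler()),
                 ("model", KNeighborsClassifier(metric="euclidean"))]
    elif family == "svm_linear":
        # Platt-style calibration supplies the [0, 1] scores a margin
        # classifier lacks natively
        steps = [("scale", StandardScaler()),
                 ("model", CalibratedClassifierCV(
                     SVC(kernel="linear", random_state=seed),
                     ensemble=False))]
    elif family == "random_forest":
        steps = [("model", RandomForestClassifier(
            n_estimators=500, random_state=seed, n_jobs=1))]
    elif family == "gbm":
        steps = [("model", GradientBoostingClassifier(
            n_estimators=150, max_depth=3, learning_rate=0.1,
            random_state=seed))]
    else:
        raise ValueError(
            f"unknown classifier family {family!r}; expected one of {CLASSIFIER_FAMILIES}")
    return Pipeline(steps)


class TunedPairClassifier:
    """Supervised pair classifier with internal cross-validated tuning.

    Hyperparameters (tree depth, k, margin penalty) are selected by
    ``inner_cv``-fold cross-validation maximizing accuracy; the tuned model
    is refitted on the full training data.  When ``compute_selection_score``
    is set, a ``selection_cv``-fold cross-validated accuracy of the tuned
    configuration is stored in ``selection_score_`` for across-family model
    selection.  Deterministic given ``seed``.

    Fitted attributes: ``best_params_``, ``estimator_``, ``classes_``,
    ``feature_names_in_``, and optionally ``selection_score_``.
    """

    def __init__(self, family: str = "random_forest", seed: int = 0,
                 inner_cv: int = 5, selection_cv: int = 10,
                 grid: dict | None = None,
                 compute_selection_score: bool = False):
        self.family = family
        self.seed = seed
        self.inner_cv = inner_cv
        self.selection_cv = selection_cv
        self.grid = grid
        self.compute_selection_score = compute_selection_score

    def get_params(self, deep: bool = True) -> dict:
        return {"family": self.family, "seed": self.seed,
                "inner_cv": self.inner_cv, "selection_cv": self.selection_cv,
                "grid": self.grid,
                "compute_selection_score": self.compute_selection_score}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "TunedPairClassifier":
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(
                f"unknown classifier family {self.family!r}; "
                f"expected one of {CLASSIFIER_FAMILIES}")
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data contains a single class")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
        else:
            self.feature_names_in_ = None
        mat = _as_matrix(X)
        grid = self.grid if self.grid is not None else _DEFAULT_GRIDS[self.family]
        pipeline = _build_pipeline(self.family, self.seed)
        n_candidates = int(np.prod([len(v) for v in grid.values()])) if grid else 1
        if n_candidates > 1:
            cv = StratifiedKFold(n_splits=self.inner_cv, shuffle=True,
                                 random_state=self.seed)
            search = GridSearchCV(pipeline, grid, scoring="accuracy", cv=cv,
                                  n_jobs=1, refit=True)
            search.fit(mat, y)
            self.best_params_ = dict(search.best_params_)
            self.estimator_ = search.best_estimator_
        else:
            params = {k: v[0] for k, v in grid.items()}
            pipeline.set_params(**params)
            pipeline.fit(mat, y)
            self.best_params_ = params
            self.estimator_ = pipeline
        if self.compute_selection_score:
            cv10 = StratifiedKFold(n_splits=self.selection_cv, shuffle=True,
                                   random_state=self.seed)
            scores = cross_val_score(self.estimator_, mat, y,
                                     scoring="accuracy", cv=cv10, n_jobs=1)
            self.selection_score_ = float(scores.mean())
        self.classes_ = classes
        self.n_features_in_ = mat.shape[1]
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "estimator_"):
            raise RuntimeError("classifier is not fitted; call fit(X, y) first")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        mat = _as_matrix(X, self.feature_names_in_)
        return self.estimator_.predict_proba(mat)

    def decision_function(self, X) -> np.ndarray:
        """Continuous class-1 score in [0, 1]."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        """Hard labels at the 0.5 score threshold."""
        return (self.decision_function(X) >= 0.5).astype(int)

    @property
    def feature_importances_(self) -> np.ndarray:
        self._check_fitted()
        model = self.estimator_.named_steps["model"]
        if not hasattr(model, "feature_importances_"):
            raise AttributeError(
                f"family {self.family!r} does not expose impurity importances")
        return model.feature_importances_


@dataclass(frozen=True)
class ImportanceReport:
    """Impurity-decrease feature importances with min-max normalizations."""

    features: tuple[str, ...]
    absolute: np.ndarray
    relative_100: np.ndarray  # min -> 0, max -> 100
    relative_unit: np.ndarray  # min -> 0, max -> 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.features,
            "importance": self.absolute,
            "relative": self.relative_100,
            "relative_unit": self.relative_unit,
        })


def feature_importance(model: TunedPairClassifier,
                       feature_names: list[str] | None = None) -> ImportanceReport:
    """Importance report for an impurity-based ensemble (random forest or
    gradient boosting)."""
    if model.family not in ("random_forest", "gbm"):
        raise ValueError(
            f"feature importance requires random_forest or gbm, got {model.family!r}")
    imp = np.asarray(model.feature_importances_, dtype=float)
    names = feature_names or model.feature_names_in_ or [
        f"f{i}" for i in range(imp.size)]
    span = imp.max() - imp.min()
    unit = (imp - imp.min()) / span if span > 0 else np.zeros_like(imp)
    return ImportanceReport(features=tuple(names), absolute=imp,
                            relative_100=unit * 100.0, relative_unit=unit)


# ---------------------------------------------------------------------------
# functional wrappers

def fit_combined(features, percentile: float = 90.0) -> CombinedSimilarityClassifier:
    return CombinedSimilarityClassifier(percentile=percentile).fit(features)


def predict_combined(model: CombinedSimilarityClassifier, features) -> pd.DataFrame:
    scores = model.decision_function(features)
    labels = model.predict(features)
    return pd.DataFrame({"score": scores, "label": labels})


def train_classifier(family: str, X, y, seed: int = 0,
                     **kwargs) -> TunedPairClassifier:
    return TunedPairClassifier(family=family, seed=seed, **kwargs).fit(X, y)


def predict_classifier(model: TunedPairClassifier, X) -> pd.DataFrame:
    scores = model.decision_function(X)
    labels = (scores >= 0.5).astype(int)
    return pd.DataFrame({"score": scores, "label": labels})
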