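"""Classifier contracts: SVM, KNN and random forest over raw beat segments.

The feature vector is the 650-sample detrended beat itself — no
feature extraction.  Model fitting is delegated to scikit-learn; this
module pins the final hyperparameter sets used throughout the
robustness experiments and exposes the successive-halving search over
the published grids.

Final per-family defaults:

* SVM — C = 1, gamma = 0.1, RBF kernel
* KNN — Euclidean metric, 5 neighbors, inverse-distance weights
* RF  — 800 trees, max depth 25, min samples split 5

Note the default SVM C = 1 lies outside the search grid's {10, 100};
both are honored as printed in the source protocol (defaults vs grid).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.experimental import enable_halving_search_cv  # noqa: F401
from sklearn.model_selection import HalvingGridSearchCV, PredefinedSplit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import InvalidArgumentError

__all__ = ["ModelSpec", "SearchGrid", "DEFAULT_HYPERPARAMETERS", "FAMILIES",
           "build_estimator", "fit", "predict", "halving_search",
           "save_model", "load_model"]

FAMILIES = ("SVM", "KNN", "RF")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "SVM": {"C": 1, "gamma": 0.1, "kernel": "rbf"},
    "KNN": {"metric": "euclidean", "n_neighbors": 5, "weights": "distance"},
    "RF": {"n_estimators": 800, "max_depth": 25, "min_samples_split": 5},
}

#: Published search grids, exactly as used by the halving search.
DEFAULT_GRIDS: dict[str, dict] = {
    "SVM": {"kernel": ["rbf", "sigmoid"], "C": [10, 100], "gamma": [0.1, 0.01, 0.001]},
    "KNN": {
        "metric": ["euclidean", "manhattan"],
        "n_neighbors": [1, 3, 5, 7, 9, 11],
        "weights": ["uniform", "distance"],
    },
    "RF": {
        "n_estimators": [200, 400, 800],
        "criterion": ["gini", "entropy"],
        "max_depth": [5, 15, 25],
        "min_samples_split": [5, 10, 15],
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family plus its hyperparameters and seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise InvalidArgumentError(f"family must be one of {FAMILIES}")
        merged = {**DEFAULT_HYPERPARAMETERS[self.family], **self.hyperparameters}
        object.__setattr__(self, "hyperparameters", merged)


@dataclass(frozen=True)
class SearchGrid:
    """Per-family halving-search grid; defaults mirror the published grids."""

    family: str
    grid: dict = field(default_factory=dict)
    halving_factor: int = 3

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise InvalidArgumentError(f"family must be one of {FAMILIES}")
        if not self.grid:
            object.__setattr__(self, "grid", DEFAULT_GRIDS[self.family])


def build_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn estimator for ``spec``."""
    hp = spec.hyperparameters
    if spec.family == "SVM":
        return SVC(random_state=spec.rng_seed, **hp)
    if spec.family == "KNN":
        return KNeighborsClassifier(**hp)
    return RandomForestClassifier(random_state=spec.rng_seed, n_jobs=1, **hp)


def fit(spec: ModelSpec, X: np.ndarray, y: np.ndarray):
    """Train one classifier; requires both classes present."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 training samples")
    if np.unique(y).size < 2:
        raise InvalidArgumentError("training labels must contain both classes")
    model = build_estimator(spec)
    model.fit(X, y)
    model._ecgrobust_spec = spec
    return model


def predict(model, X: np.ndarray) -> np.ndarray:
    """Per-row label predictions; validates the feature dimension."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.array([], dtype=object)
    if X.shape[1] != model.n_features_in_:
        raise InvalidArgumentError(
            f"feature dimension {X.shape[1]} != training dimension {model.n_features_in_}"
        )
    return model.predict(X)


def halving_search(
    grid: SearchGrid,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    *,
    rng_seed: int = 0,
) -> tuple[ModelSpec, "HalvingGridSearchCV"]:
    """Successive-halving grid search validated on a held-out set.

    Candidates are scored on the fixed validation split while the
    training resource (sample count) grows by ``halving_factor`` per
    iteration and the candidate pool shrinks by the same factor.
    Returns the winning :class:`ModelSpec` and the fitted searcher.
    """
    if not grid.grid:
        raise InvalidArgumentError("empty search grid")
    X = np.vstack([X_train, X_val])
    y = np.concatenate([np.asarray(y_train), np.asarray(y_val)])
    test_fold = np.r_[np.full(len(y_train), -1), np.zeros(len(y_val))]
    base = build_estimator(ModelSpec(grid.family, rng_seed=rng_seed))
    searcher = HalvingGridSearchCV(
        base,
        grid.grid,
        factor=grid.halving_factor,
        resource="n_samples",
        min_resources="exhaust",
        cv=PredefinedSplit(test_fold),
        scoring="accuracy",
        refit=False,
        random_state=rng_seed,
    )
    searcher.fit(X, y)
    return ModelSpec(grid.family, dict(searcher.best_params_), rng_seed=rng_seed), searcher


def save_model(model, path: str | Path) -> None:
    """Serialize a trained model plus a JSON manifest alongside it."""
    path = Path(path)
    joblib.dump(model, path)
    spec: ModelSpec | None = getattr(model, "_ecgrobust_spec", None)
    manifest = {
        "family": spec.family if spec else type(model).__name__,
        "hyperparameters": spec.hyperparameters if spec else {},
        "rng_seed": spec.rng_seed if spec else None,
        "n_features": int(getattr(model, "n_features_in_", 0)),
        "classes": [str(c) for c in getattr(model, "classes_", [])],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=2))


def load_model(path: str | Path):
    return joblib.load(path)
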