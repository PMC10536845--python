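"""Model benchmarking, cross-validation and the K-neighbors activity model.

Ten regression learners sit behind a registry; each is benchmarked with
10-fold cross-validation on identical folds and ranked by mean R² (RMSE as
tie-break). Only the K-neighbors regressor — the selected model — has its
predictive semantics pinned exactly here (Minkowski-p distance, uniform or
inverse-distance weights, deterministic lowest-index tie-break at the k-th
neighbour distance); the other learners are library-backed.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.model_selection import KFold

from .exceptions import ParameterError, ProvenanceError, StateError

DEFAULT_SEED = 42
MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# folds and metrics
# ---------------------------------------------------------------------------

def kfold_split(n: int, k: int = 10, seed: int = DEFAULT_SEED) -> np.ndarray:
    """Seed-deterministic shuffled k-fold assignment: an array of fold labels
    in 0..k−1, each index in exactly one test fold, fold sizes within 1."""
    if n < k:
        raise ParameterError(f"cannot split n={n} samples into k={k} folds")
    labels = np.empty(n, dtype=int)
    for fold, (_, test) in enumerate(
        KFold(n_splits=k, shuffle=True, random_state=seed).split(np.empty((n, 1)))
    ):
        labels[test] = fold
    return labels


@dataclass
class CVMetrics:
    """Per-fold and aggregate cross-validation metrics (R², MSE, MAE, RMSE).

    Aggregates use the arithmetic mean and the sample (n−1) standard
    deviation; any rounding happens only at presentation time."""

    per_fold: pd.DataFrame
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.per_fold)

    @classmethod
    def from_folds(cls, per_fold: pd.DataFrame) -> "CVMetrics":
        mean, sd = aggregate_metrics(per_fold)
        return cls(per_fold=per_fold, mean=mean, sd=sd)


def aggregate_metrics(per_fold: pd.DataFrame) -> tuple[dict, dict]:
    """Mean and sample SD of each metric column over folds."""
    if len(per_fold) < 2:
        raise ParameterError("aggregation needs at least 2 folds")
    mean = {c: float(np.mean(per_fold[c])) for c in per_fold.columns}
    sd = {c: float(np.std(per_fold[c], ddof=1)) for c in per_fold.columns}
    return mean, sd


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

    mse = mean_squared_error(y_true, y_pred)
    out = {
        "mse": mse,
        "mae": mean_absolute_error(y_true, y_pred),
        "rmse": float(np.sqrt(mse)),
    }
    if np.std(y_true) == 0:
        warnings.warn("constant-target fold: R² undefined, reported as NaN")
        out["r2"] = float("nan")
    else:
        out["r2"] = r2_score(y_true, y_pred)
    return out


# ---------------------------------------------------------------------------
# the K-neighbors model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KNNSpec:
    """K-neighbors hyperparameters. ``leaf_size`` tunes search structures
    only and never changes predictions."""

    n_neighbors: int = 5
    p: float = 2
    weights: str = "uniform"
    leaf_size: int = 30

    def __post_init__(self):
        if self.n_neighbors < 1:
            raise ParameterError("n_neighbors must be at least 1")
        if self.p < 1:
            raise ParameterError("Minkowski exponent p must be at least 1")
        if self.weights not in ("uniform", "distance"):
            raise ParameterError("weights must be 'uniform' or 'distance'")


class KNeighborsActivityRegressor(BaseEstimator, RegressorMixin):
    """K-nearest-neighbours pIC50 regression under Minkowski-p distance.

    Uniform weights average the k nearest labels; distance weights use
    inverse-distance weighting, with an exact match (distance 0) returning
    that training label. Neighbour ties at the k-th distance are broken by
    lowest training index, making predictions fully deterministic.
    """

    def __init__(self, n_neighbors: int = 5, p: float = 2,
                 weights: str = "uniform", leaf_size: int = 30):
        self.n_neighbors = n_neighbors
        self.p = p
        self.weights = weights
        self.leaf_size = leaf_size

    @property
    def spec(self) -> KNNSpec:
        return KNNSpec(self.n_neighbors, self.p, self.weights, self.leaf_size)

    def fit(self, X, y):
        self.spec  # validates hyperparameters
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(X) == 0:
            raise StateError("cannot fit on an empty training set")
        if self.n_neighbors > len(X):
            raise ParameterError(
                f"n_neighbors={self.n_neighbors} exceeds training size {len(X)}"
            )
        self.X_ = X
        self.y_ = y
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "X_"):
            raise StateError("model is not fitted")
        from scipy.spatial.distance import cdist

        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        d = cdist(X, self.X_, metric="minkowski", p=self.p)
        out = np.empty(len(X))
        order_idx = np.arange(len(self.X_))
        for i in range(len(X)):
            order = np.lexsort((order_idx, d[i]))  # distance, then lowest index
            nearest = order[: self.n_neighbors]
            dist = d[i][nearest]
            if self.weights == "uniform":
                out[i] = self.y_[nearest].mean()
            else:
                exact = dist == 0.0
                if exact.any():
                    out[i] = self.y_[nearest[exact][0]]
                else:
                    w = 1.0 / dist
                    out[i] = float(np.average(self.y_[nearest], weights=w))
        return out


def knn_predict(train_X, train_y, query, spec: KNNSpec = KNNSpec()) -> float | np.ndarray:
    """Functional wrapper over :class:`KNeighborsActivityRegressor`."""
    model = KNeighborsActivityRegressor(
        spec.n_neighbors, spec.p, spec.weights, spec.leaf_size
    ).fit(train_X, train_y)
    query = np.asarray(query, dtype=float)
    pred = model.predict(query)
    return float(pred[0]) if query.ndim == 1 else pred


# ---------------------------------------------------------------------------
# learner registry
# ---------------------------------------------------------------------------

def _registry_factories(seed: int) -> dict:
    from sklearn.ensemble import (
        AdaBoostRegressor, ExtraTreesRegressor, HistGradientBoostingRegressor,
        RandomForestRegressor,
    )
    from sklearn.linear_model import SGDRegressor
    from sklearn.neural_network import MLPRegressor
    from sklearn.tree import DecisionTreeRegressor

    def lgbm():
        from lightgbm import LGBMRegressor

        return LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1)

    def xgb():
        from xgboost import XGBRegressor

        return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0)

    return {
        "k_neighbors": lambda: KNeighborsActivityRegressor(),
        "random_forest": lambda: RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1),
        "extra_trees": lambda: ExtraTreesRegressor(n_estimators=100, random_state=seed, n_jobs=1),
        "light_gradient_boosting": lgbm,
        "histogram_gradient_boosting": lambda: HistGradientBoostingRegressor(random_state=seed),
        "extreme_gradient_boosting": xgb,
        "decision_tree": lambda: DecisionTreeRegressor(random_state=seed),
        "stochastic_gradient_descent": lambda: SGDRegressor(random_state=seed, max_iter=2000),
        "multilayer_perceptron": lambda: MLPRegressor(
            hidden_layer_sizes=(64,), max_iter=400, random_state=seed
        ),
        "adaptive_boosting": lambda: AdaBoostRegressor(random_state=seed),
    }


def default_registry(seed: int = DEFAULT_SEED, names=None) -> dict:
    """The ten benchmark learners as name → unfitted estimator instances."""
    factories = _registry_factories(seed)
    if names is None:
        names = list(factories)
    unknown = set(names) - set(factories)
    if unknown:
        raise ParameterError(f"unknown learner(s): {sorted(unknown)}")
    return {name: factories[name]() for name in names}


# ---------------------------------------------------------------------------
# cross-validation, benchmarking, grid search
# ---------------------------------------------------------------------------

def cross_validate(learner, X, y, k: int = 10, seed: int = DEFAULT_SEED) -> CVMetrics:
    """k-fold CV with per-fold metrics computed on held-out data only."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = kfold_split(len(X), k, seed)
    rows = []
    for fold in range(k):
        test = folds == fold
        model = clone(learner).fit(X[~test], y[~test])
        rows.append(_fold_metrics(y[test], model.predict(X[test])))
    per_fold = pd.DataFrame(rows, index=pd.RangeIndex(k, name="fold"))
    return CVMetrics.from_folds(per_fold[["r2", "mse", "mae", "rmse"]])


def cv_predictions(learner, X, y, k: int = 10, seed: int = DEFAULT_SEED) -> np.ndarray:
    """Held-out prediction for every sample under the same fold protocol."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = kfold_split(len(X), k, seed)
    yhat = np.empty(len(y))
    for fold in range(k):
        test = folds == fold
        model = clone(learner).fit(X[~test], y[~test])
        yhat[test] = model.predict(X[test])
    return yhat


def benchmark(registry: dict, X, y, k: int = 10, seed: int = DEFAULT_SEED) -> pd.DataFrame:
    """Cross-validate every registry learner on identical folds and rank by
    mean R² descending (RMSE ascending breaks ties). Learner failures are
    recorded as failed rows; the run continues."""
    if not registry:
        raise ParameterError("learner registry is empty")
    rows = []
    details = {}
    for name, learner in registry.items():
        try:
            metrics = cross_validate(learner, X, y, k=k, seed=seed)
        except Exception as exc:  # noqa: BLE001 - failures become report rows
            rows.append({"algorithm": name, "r2": np.nan, "rmse": np.nan,
                         "mae": np.nan, "status": f"failed: {exc}"})
            continue
        details[name] = metrics
        rows.append({
            "algorithm": name,
            "r2": metrics.mean["r2"],
            "rmse": metrics.mean["rmse"],
            "mae": metrics.mean["mae"],
            "status": "ok",
        })
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["r2", "rmse"], ascending=[False, True], na_position="last", kind="stable"
    ).reset_index(drop=True)
    table.attrs["cv_metrics"] = details
    return table


def grid_search(
    X, y,
    n_neighbors_range=range(2, 33),
    p_range=range(1, 11),
    weights_options=("uniform", "distance"),
    leaf_sizes=range(5, 51, 5),
    k: int = 10,
    seed: int = DEFAULT_SEED,
) -> tuple[KNNSpec, pd.DataFrame]:
    """Exhaustive K-neighbors hyperparameter search by mean CV R².

    leaf_size never affects predictions, so each prediction-relevant
    (n_neighbors, p, weights) cell is evaluated once and shared across leaf
    sizes. Ties prefer smaller n_neighbors, then smaller p. Returns the best
    spec and the full results table."""
    cells = [
        (n, p, w)
        for n in n_neighbors_range for p in p_range for w in weights_options
    ]
    if not cells or len(list(leaf_sizes)) == 0:
        raise ParameterError("grid is empty")
    results = []
    for n, p, w in cells:
        metrics = cross_validate(
            KNeighborsActivityRegressor(n_neighbors=n, p=p, weights=w), X, y, k=k, seed=seed
        )
        results.append({"n_neighbors": n, "p": p, "weights": w,
                        "mean_r2": metrics.mean["r2"], "mean_rmse": metrics.mean["rmse"]})
    table = pd.DataFrame(results)
    best_row = table.sort_values(
        ["mean_r2", "n_neighbors", "p"], ascending=[False, True, True], kind="stable"
    ).iloc[0]
    best = KNNSpec(
        n_neighbors=int(best_row["n_neighbors"]),
        p=float(best_row["p"]),
        weights=str(best_row["weights"]),
        leaf_size=min(leaf_sizes),
    )
    return best, table


# ---------------------------------------------------------------------------
# persistence (portable JSON, integrity- and provenance-checked)
# ---------------------------------------------------------------------------

def _training_hash(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=float).tobytes())
    h.update(np.ascontiguousarray(y, dtype=float).tobytes())
    return h.hexdigest()


def save_model(model: KNeighborsActivityRegressor, path, featurizer_provenance: dict) -> None:
    """Persist a fitted K-neighbors model as a single JSON document carrying
    its hyperparameters, training data, featurizer provenance and a SHA-256
    training-data hash (refused on mismatch at load time)."""
    if not hasattr(model, "X_"):
        raise StateError("cannot save an unfitted model")
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "model": "k_neighbors",
        "spec": {
            "n_neighbors": model.n_neighbors,
            "p": model.p,
            "weights": model.weights,
            "leaf_size": model.leaf_size,
        },
        "featurizer": featurizer_provenance,
        "training_hash": _training_hash(model.X_, model.y_),
        "X": model.X_.tolist(),
        "y": model.y_.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> tuple[KNeighborsActivityRegressor, dict]:
    """Load a persisted model, verifying format version and training hash.
    Returns (fitted model, featurizer provenance)."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ProvenanceError(
            f"incompatible model format version {doc.get('format_version')!r}, "
            f"expected {MODEL_FORMAT_VERSION}"
        )
    X = np.asarray(doc["X"], dtype=float)
    y = np.asarray(doc["y"], dtype=float)
    if _training_hash(X, y) != doc.get("training_hash"):
        raise ProvenanceError("training-data hash mismatch: model file corrupted or tampered")
    spec = doc["spec"]
    model = KNeighborsActivityRegressor(
        n_neighbors=spec["n_neighbors"], p=spec["p"],
        weights=spec["weights"], leaf_size=spec["leaf_size"],
    ).fit(X, y)
    return model, doc["featurizer"]


def check_featurizer_match(saved: dict, current: dict) -> None:
    """Refuse predictions when a model's stored featurizer provenance differs
    from the featurizer used for the queries."""
    keys = set(saved) | set(current)
    mismatched = {k for k in keys if saved.get(k) != current.get(k)}
    if mismatched:
        raise ProvenanceError(
            f"featurizer provenance mismatch on {sorted(mismatched)}: "
            f"saved={saved}, current={current}"
        )
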