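"""Training, tuning and prediction for the six benchmark classifiers.

Methods: linear discriminant analysis (lda), decision tree (dt),
RBF-kernel support vector machine (svm), random forest (rf), a
single-hidden-layer artificial neural network (ann) and extreme
gradient boosting (xgboost). scikit-learn and xgboost provide the
fitting backends; this module owns the surrounding conventions:

* LDA suffers from correlated inputs, so the full feature catalogue is
  pruned first with an iterative |r| > 0.7 cut (``prune_correlated_features``);
* SVM and ANN see standardised features (centre/scale stored on the
  trained model and applied at prediction);
* RF predicts by majority vote over per-tree class predictions with an
  alphabetical tie-break — the classical forest voting rule, shared
  with the compact on-board engine;
* seeds are explicit everywhere; no hidden global RNG state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = [
    "METHODS",
    "TuningGrid",
    "TrainedClassifier",
    "default_hyperparams",
    "default_grid",
    "prune_correlated_features",
    "tune_classifier",
    "train_classifier",
    "predict",
    "save_model",
    "load_model",
]

METHODS = ("lda", "dt", "svm", "rf", "ann", "xgboost")

#: tunable hyperparameters per method (candidates must be positive where noted)
_METHOD_PARAMS = {
    "lda": set(),
    "dt": {"cp"},
    "svm": {"gamma", "cost"},
    "rf": {"mtry", "ntree"},
    "ann": {"size", "decay"},
    "xgboost": {"nrounds", "max_depth"},
}

# direction of "simpler" for tie-breaking during tuning: -1 = smaller is
# simpler, +1 = larger is simpler (stronger regularisation)
_SIMPLER = {"cp": +1, "gamma": -1, "cost": -1, "mtry": -1, "ntree": -1,
            "size": -1, "decay": +1, "nrounds": -1, "max_depth": -1}


@dataclass
class TuningGrid:
    """Candidate hyperparameter values for one method's grid search."""

    method: str
    params: dict[str, list]

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        extra = set(self.params) - _METHOD_PARAMS[self.method]
        if extra:
            raise ValidationError(
                f"parameters {sorted(extra)} do not belong to {self.method}"
            )
        for name, values in self.params.items():
            if not values:
                raise ValidationError(f"empty candidate list for {name!r}")
            if any(v <= 0 for v in values) and name != "cp":
                raise ValidationError(f"candidates for {name!r} must be positive")

    def candidates(self) -> list[dict]:
        names = sorted(self.params)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.params[n] for n in names))
        ]


def default_hyperparams(method: str, set_kind: str = "full") -> dict:
    """Sensible defaults per method.

    Ensemble sizes follow the model-shrinking convention for on-board
    use: rf ntree = 800 and xgboost nrounds = 10 on the full feature
    set, ntree = 20 and nrounds = 5 on the simplified sets.
    """
    if method == "lda":
        return {}
    if method == "dt":
        return {"cp": 0.0}
    if method == "svm":
        return {"gamma": 0.1, "cost": 10.0}
    if method == "rf":
        return {"ntree": 800 if set_kind == "full" else 20, "mtry": 0}
    if method == "ann":
        return {"size": 8, "decay": 1e-3}
    if method == "xgboost":
        return {"nrounds": 10 if set_kind == "full" else 5, "max_depth": 6}
    raise ValidationError(f"unknown method {method!r}")


def default_grid(method: str) -> TuningGrid:
    """Config-exposed default tuning grids (small, implementer-chosen)."""
    grids = {
        "lda": {},
        "dt": {"cp": [0.0, 0.001, 0.01]},
        "svm": {"gamma": [0.01, 0.1, 1.0], "cost": [1.0, 10.0, 100.0]},
        "rf": {"ntree": [100, 400, 800], "mtry": [0]},
        "ann": {"size": [4, 8, 16], "decay": [1e-4, 1e-3, 1e-2]},
        "xgboost": {"nrounds": [10], "max_depth": [6]},
    }
    return TuningGrid(method=method, params=grids[method])


@dataclass
class TrainedClassifier:
    """A fitted model plus everything prediction needs.

    ``feature_names`` is the input contract; ``used_features`` may be a
    subset after LDA's correlation pruning. ``scaler`` holds the
    per-feature (centre, scale) applied before SVM and ANN prediction.
    """

    method: str
    backend: object
    feature_names: tuple[str, ...]
    used_features: tuple[str, ...]
    class_labels: tuple[str, ...]
    hyperparams: dict
    scaler: tuple[np.ndarray, np.ndarray] | None = None
    seed: int = 0


# ---------------------------------------------------------------------------
# correlation pruning (the findCorrelation-style iteration used before LDA)
# ---------------------------------------------------------------------------

def prune_correlated_features(
    X: pd.DataFrame, cutoff: float = 0.7
) -> list[str]:
    """Drop features until no pairwise |Pearson r| exceeds ``cutoff``.

    Iteratively: take the remaining pair with the largest |r| and remove
    the member with the larger mean absolute correlation against all
    remaining features (ties keep the earlier column). Constant columns
    have undefined correlations, treated as 0, so they are never removed
    for constancy alone. Returns surviving names in original order; the
    procedure is idempotent.
    """
    if X.shape[1] < 2:
        raise ValidationError("need at least 2 features to prune")
    if not 0 < cutoff < 1:
        raise ValidationError("cutoff must lie in (0, 1)")
    names = list(X.columns)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(np.corrcoef(X.to_numpy(dtype=float), rowvar=False))
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 0.0)
    alive = np.ones(len(names), dtype=bool)
    while True:
        sub = np.where(np.outer(alive, alive), r, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= cutoff:
            break
        mean_i = sub[i, alive].mean()
        mean_j = sub[j, alive].mean()
        # remove the member more entangled with everything else;
        # on a tie keep the earlier (lower-index) column
        drop = i if mean_i > mean_j else j if mean_j > mean_i else max(i, j)
        alive[drop] = False
    return [n for n, keep in zip(names, alive) if keep]


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------

def _check_finite(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        r, c = np.argwhere(~np.isfinite(arr))[0]
        raise ValidationError(
            f"non-finite value in feature {X.columns[c]!r} at bout row {X.index[r]}"
        )


def _standardize_fit(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = arr.mean(axis=0)
    scale = arr.std(axis=0)
    scale[scale == 0] = 1.0
    return center, scale


def train_classifier(
    method: str,
    X: pd.DataFrame,
    y: Sequence[str],
    hyperparams: dict | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit one classifier on a feature table (rows = bouts).

    ``hyperparams`` defaults to :func:`default_hyperparams` for the full
    feature set. For rf, ``mtry = 0`` means the backend's default
    (sqrt of the feature count).
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier
    from xgboost import XGBClassifier

    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}")
    if not isinstance(X, pd.DataFrame):
        raise ValidationError("X must be a DataFrame of named features")
    _check_finite(X)
    y = np.asarray(y, dtype=object)
    classes = tuple(sorted(set(map(str, y))))
    if len(classes) < 2:
        raise ValidationError("need at least 2 behaviour classes to train")
    hp = {**default_hyperparams(method), **(hyperparams or {})}
    extra = set(hp) - _METHOD_PARAMS[method]
    if extra:
        raise ValidationError(f"parameters {sorted(extra)} do not belong to {method}")

    feature_names = tuple(X.columns)
    used = feature_names
    scaler = None
    arr = X.to_numpy(dtype=float)

    if method == "lda":
        if len(feature_names) >= 2:
            used = tuple(prune_correlated_features(X))
            arr = X[list(used)].to_numpy(dtype=float)
        backend = LinearDiscriminantAnalysis().fit(arr, y)
    elif method == "dt":
        backend = DecisionTreeClassifier(
            ccp_alpha=hp["cp"], random_state=seed
        ).fit(arr, y)
    elif method == "svm":
        scaler = _standardize_fit(arr)
        arr = (arr - scaler[0]) / scaler[1]
        backend = SVC(kernel="rbf", gamma=hp["gamma"], C=hp["cost"]).fit(arr, y)
    elif method == "rf":
        mtry = hp["mtry"] or "sqrt"
        backend = RandomForestClassifier(
            n_estimators=hp["ntree"],
            max_features=mtry,
            random_state=seed,
            n_jobs=1,
        ).fit(arr, y)
    elif method == "ann":
        scaler = _standardize_fit(arr)
        arr = (arr - scaler[0]) / scaler[1]
        backend = MLPClassifier(
            hidden_layer_sizes=(hp["size"],),
            activation="logistic",
            alpha=hp["decay"],
            solver="lbfgs",
            max_iter=500,
            random_state=seed,
        ).fit(arr, y)
    else:  # xgboost
        encoded = np.array([classes.index(v) for v in map(str, y)])
        backend = XGBClassifier(
            n_estimators=hp["nrounds"],
            max_depth=hp["max_depth"],
            objective="multi:softprob",
            num_class=len(classes),
            base_score=0.5,
            random_state=seed,
            n_jobs=1,
        ).fit(arr, encoded)

    return TrainedClassifier(
        method=method,
        backend=backend,
        feature_names=feature_names,
        used_features=used,
        class_labels=classes,
        hyperparams=hp,
        scaler=scaler,
        seed=seed,
    )


def predict(model: TrainedClassifier, X: pd.DataFrame) -> np.ndarray:
    """Predict one behaviour label per row.

    Columns must match the model's feature names (any order); missing
    or extra columns are reported by name.
    """
    missing = set(model.feature_names) - set(X.columns)
    extra = set(X.columns) - set(model.feature_names)
    if missing or extra:
        raise ValidationError(
            f"feature columns mismatch: missing {sorted(missing)}, "
            f"extra {sorted(extra)}"
        )
    X = X[list(model.feature_names)]
    _check_finite(X)
    arr = X[list(model.used_features)].to_numpy(dtype=float)
    if model.scaler is not None:
        arr = (arr - model.scaler[0]) / model.scaler[1]
    if model.method == "rf":
        # classical forest voting: one class vote per tree, alphabetical
        # tie-break (argmax picks the lowest class index)
        backend = model.backend
        votes = np.stack(
            [est.predict(arr).astype(int) for est in backend.estimators_]
        )
        k = len(backend.classes_)
        counts = np.apply_along_axis(
            lambda col: np.bincount(col, minlength=k), 0, votes
        )
        return np.asarray(backend.classes_[counts.argmax(axis=0)], dtype=object)
    if model.method == "xgboost":
        pred = np.asarray(model.backend.predict(arr))
        if pred.ndim == 2:  # softprob output: argmax over class columns
            pred = pred.argmax(axis=1)
        return np.array([model.class_labels[int(i)] for i in pred], dtype=object)
    return np.asarray(model.backend.predict(arr), dtype=object)


def tune_classifier(
    method: str,
    X: pd.DataFrame,
    y: Sequence[str],
    grid: TuningGrid | None = None,
    k: int = 10,
    seed: int = 0,
) -> dict:
    """Grid search maximising mean stratified-CV overall accuracy.

    Ties go to the simpler model (smaller size/ntree/cost/gamma/
    nrounds/mtry, larger decay/cp). Returns the winning hyperparameters.
    """
    from .evaluate import cross_validate  # deferred: evaluate trains via us

    grid = grid or default_grid(method)
    if grid.method != method:
        raise ValidationError("grid method does not match")
    best = None
    for cand in grid.candidates():
        report = cross_validate(method, X, y, cand, k=k, seed=seed)
        # larger key = simpler; sign per parameter encodes which direction is simpler
        simplicity = tuple(
            _SIMPLER[name] * cand[name] for name in sorted(cand)
        )
        key = (report.mean_accuracy, simplicity)
        if best is None or key > best[0]:
            best = (key, cand)
    if best is None:
        raise ValidationError("empty tuning grid")
    return best[1]


# ---------------------------------------------------------------------------
# serialization: a JSON-able header plus the opaque backend payload
# ---------------------------------------------------------------------------

def save_model(model: TrainedClassifier, path) -> None:
    import joblib

    header = {
        "method": model.method,
        "feature_names": list(model.feature_names),
        "used_features": list(model.used_features),
        "class_labels": list(model.class_labels),
        "hyperparams": model.hyperparams,
        "scaler": None
        if model.scaler is None
        else [model.scaler[0].tolist(), model.scaler[1].tolist()],
        "seed": model.seed,
    }
    joblib.dump({"header": header, "payload": model.backend}, path)


def load_model(path) -> TrainedClassifier:
    import joblib

    blob = joblib.load(path)
    h = blob["header"]
    scaler = h["scaler"]
    return TrainedClassifier(
        method=h["method"],
        backend=blob["payload"],
        feature_names=tuple(h["feature_names"]),
        used_features=tuple(h["used_features"]),
        class_labels=tuple(h["class_labels"]),
        hyperparams=h["hyperparams"],
        scaler=None if scaler is None else (np.array(scaler[0]), np.array(scaler[1])),
        seed=h["seed"],
    )
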