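"""The six regression scoring functions, in BA- and RMSD-response modes.

A scoring function here is a regressor mapping the feature vector of one
protein-ligand pose to either the experimental binding affinity (BA mode —
trainable on native poses only, since affinities exist only for natives) or
the pose's RMSD from the native pose (RMSD mode — trainable on every decoy,
so the training table scales with poses per complex). Poses are then ranked
by descending predicted affinity or ascending predicted RMSD.

Methods: multiple linear regression (MLR), multivariate adaptive regression
splines (MARS), k-nearest neighbours (kNN), support-vector regression with
an RBF kernel (SVM), random forests (RF, 2000 trees, mtry tuned out-of-bag)
and boosted regression trees (BRT, shrinkage fixed at 0.005, tree count
selected by internal cross-validation). Published tuned hyperparameter
values per feature-family combination ship in ``data/tuned_params.json``.

Feature standardisation (zero mean / unit variance, fitted on the training
table) is applied for kNN and SVM only; linear and tree methods see raw
features. The SVM kernel width is parameterised as sigma with
gamma = 1/(2 sigma^2).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from ._mars import MarsRegressor
from .geomfeat import FeatureFamilySelection, feature_columns

__all__ = [
    "METHODS",
    "DEFAULT_SEED",
    "RF_N_TREES",
    "BRT_SHRINKAGE",
    "ScoringModel",
    "default_grid",
    "table1_params",
    "tune",
    "fit",
    "predict",
    "rank_poses",
    "save_model",
    "load_model",
]

METHODS = ("mlr", "mars", "knn", "svm", "rf", "brt")
RESPONSES = ("BA", "RMSD")
DEFAULT_SEED = 20070101

#: fixed constants, not tuned
RF_N_TREES = 2000
BRT_SHRINKAGE = 0.005

_STANDARDIZED = {"knn", "svm"}


class ConfigurationError(ValueError):
    """Invalid method/grid/parameter configuration."""


# ---------------------------------------------------------------------------
# published tuned parameters


def table1_params(method: str, features: str | FeatureFamilySelection) -> dict:
    """Published tuned hyperparameters for a method/feature-set pair."""
    method = method.lower()
    label = features.label if isinstance(features, FeatureFamilySelection) else (
        FeatureFamilySelection(features).label
    )
    with resources.files("poseforge.data").joinpath("tuned_params.json").open() as fh:
        data = json.load(fh)
    if method == "mlr":
        return {}
    if method not in data:
        raise ConfigurationError(f"no published parameters for method {method!r}")
    idx = data["feature_sets"].index(label)
    return {param: values[idx] for param, values in data[method].items()}


def default_grid(method: str) -> dict[str, list]:
    """Search ranges matching the published tuning protocol's parameter sets."""
    method = method.lower()
    grids: dict[str, dict[str, list]] = {
        "mlr": {},
        "mars": {"degree": [1, 2], "penalty": [2, 3, 4, 5, 6, 7]},
        "knn": {"k": list(range(3, 21)), "q": [1, 2]},
        "svm": {
            "C": [1, 2, 4],
            "epsilon": [0.0, 0.125, 0.25, 0.5],
            "sigma": [0.031, 0.125, 0.25, 1.0],
        },
        "rf": {"mtry": [1, 2, 3, 5, 7, 10, 14, 18, 25, 35]},
        "brt": {"interaction_depth": [2, 5, 10, 15, 20]},
    }
    if method not in grids:
        raise ConfigurationError(f"unknown method {method!r}")
    return grids[method]


# ---------------------------------------------------------------------------
# estimator construction


def _make_estimator(method: str, params: Mapping, n_features: int, seed: int):
    method = method.lower()
    if method == "mlr":
        return LinearRegression()
    if method == "mars":
        return MarsRegressor(
            degree=int(params.get("degree", 1)),
            penalty=float(params.get("penalty", 3)),
        )
    if method == "knn":
        return KNeighborsRegressor(
            n_neighbors=int(params.get("k", 5)),
            p=int(params.get("q", 1)),
            metric="minkowski",
        )
    if method == "svm":
        sigma = float(params.get("sigma", 0.25))
        return SVR(
            kernel="rbf",
            C=float(params.get("C", 1.0)),
            epsilon=float(params.get("epsilon", 0.125)),
            gamma=1.0 / (2.0 * sigma**2),
        )
    if method == "rf":
        mtry = int(params.get("mtry", max(1, n_features // 3)))
        return RandomForestRegressor(
            n_estimators=RF_N_TREES,
            max_features=min(mtry, n_features),
            random_state=seed,
            n_jobs=1,
        )
    if method == "brt":
        # gbm's interaction.depth is the number of splits per tree; the
        # closest sklearn control is max_leaf_nodes = depth + 1
        depth = int(params.get("interaction_depth", 5))
        n_trees = int(params.get("n_trees", 1000))
        return GradientBoostingRegressor(
            n_estimators=n_trees,
            learning_rate=BRT_SHRINKAGE,
            max_leaf_nodes=depth + 1,
            max_depth=None,
            random_state=seed,
        )
    raise ConfigurationError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# the fitted-model container


@dataclass
class ScoringModel:
    """A fitted scoring function with its full training fingerprint."""

    method: str
    response: str
    family_selection: FeatureFamilySelection
    params: dict
    feature_names: list[str]
    estimator: object
    scaler: StandardScaler | None
    seed: int
    n_training_rows: int

    def _matrix(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in table.columns]
        if missing:
            raise ConfigurationError(
                f"table lacks feature columns of the training signature: {missing[:5]}"
            )
        X = table[self.feature_names].to_numpy(dtype=np.float64)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return X


def _design(
    table: pd.DataFrame,
    response: str,
    feature_cols: Sequence[str] | None,
    selection: FeatureFamilySelection | None,
) -> tuple[pd.DataFrame, list[str]]:
    if response not in RESPONSES:
        raise ConfigurationError(f"response must be one of {RESPONSES}, got {response!r}")
    if feature_cols is None:
        sel = selection or FeatureFamilySelection(
            {c.split(".")[0] for c in table.columns if "." in c and c.split(".")[0] in "XARG"}
        )
        feature_cols = feature_columns(table, sel)
    rows = table.dropna(subset=[response])
    X = rows[list(feature_cols)]
    if not np.isfinite(X.to_numpy(dtype=np.float64)).all():
        bad = rows.index[~np.isfinite(X.to_numpy(dtype=np.float64)).all(axis=1)]
        raise ValueError(f"non-finite features in rows {list(bad[:10])}")
    return rows, list(feature_cols)


def fit(
    table: pd.DataFrame,
    method: str,
    response: str = "RMSD",
    params: Mapping | None = None,
    seed: int = DEFAULT_SEED,
    feature_cols: Sequence[str] | None = None,
    selection: FeatureFamilySelection | str | None = None,
) -> ScoringModel:
    """Fit one scoring function.

    BA mode automatically restricts to rows where BA is defined (native
    poses); RMSD mode uses every row.
    """
    method = method.lower()
    if isinstance(selection, str):
        selection = FeatureFamilySelection(selection)
    rows, cols = _design(table, response, feature_cols, selection)
    if len(rows) < 2:
        raise ValueError(f"too few training rows ({len(rows)}) with {response} defined")
    X = rows[cols].to_numpy(dtype=np.float64)
    y = rows[response].to_numpy(dtype=np.float64)

    scaler = None
    if method in _STANDARDIZED:
        scaler = StandardScaler().fit(X)
        # constant columns get unit scale so they stay finite
        scaler.scale_[scaler.scale_ == 0] = 1.0
        X = scaler.transform(X)

    params = dict(params or {})
    if method == "brt" and "n_trees" not in params:
        params["n_trees"] = _brt_select_n_trees(X, y, params, seed)

    est = _make_estimator(method, params, X.shape[1], seed)
    est.fit(X, y)
    fam = selection or FeatureFamilySelection(
        {c.split(".")[0] for c in cols if c.split(".")[0] in "XARG"} or {"R"}
    )
    return ScoringModel(
        method=method,
        response=response,
        family_selection=fam,
        params=params,
        feature_names=cols,
        estimator=est,
        scaler=scaler,
        seed=seed,
        n_training_rows=len(rows),
    )


def _brt_select_n_trees(
    X: np.ndarray,
    y: np.ndarray,
    params: Mapping,
    seed: int,
    max_trees: int = 3000,
    n_folds: int = 5,
) -> int:
    """Internal 5-fold CV over the boosting path to pick the tree count."""
    n = len(y)
    folds = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=seed)
    err = np.zeros(max_trees)
    for tr, va in folds.split(X):
        est = _make_estimator("brt", {**params, "n_trees": max_trees}, X.shape[1], seed)
        est.fit(X[tr], y[tr])
        for i, pred in enumerate(est.staged_predict(X[va])):
            err[i] += np.mean((pred - y[va]) ** 2)
    return int(np.argmin(err)) + 1


def tune(
    table: pd.DataFrame,
    method: str,
    grid: Mapping[str, Sequence] | None = None,
    response: str = "BA",
    seed: int = DEFAULT_SEED,
    feature_cols: Sequence[str] | None = None,
    selection: FeatureFamilySelection | str | None = None,
    n_folds: int = 10,
) -> dict:
    """Grid search minimising MSE: 10-fold CV, except RF which tunes mtry
    on out-of-bag error. Deterministic under ``seed``; ties resolve to the
    smallest parameter tuple in the grid's key order."""
    method = method.lower()
    if method == "mlr":
        return {}
    grid = dict(grid if grid is not None else default_grid(method))
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ConfigurationError("empty hyperparameter grid")
    if isinstance(selection, str):
        selection = FeatureFamilySelection(selection)
    rows, cols = _design(table, response, feature_cols, selection)
    if len(rows) < 20:
        raise ValueError(f"tuning requires >= 20 rows, got {len(rows)}")
    X = rows[cols].to_numpy(dtype=np.float64)
    y = rows[response].to_numpy(dtype=np.float64)
    if method in _STANDARDIZED:
        scaler = StandardScaler().fit(X)
        scaler.scale_[scaler.scale_ == 0] = 1.0
        X = scaler.transform(X)

    keys = list(grid)
    combos = [dict(zip(keys, values)) for values in itertools.product(*(grid[k] for k in keys))]
    if len(combos) == 1:
        return combos[0]

    def score(params: dict) -> float:
        if method == "rf":
            est = RandomForestRegressor(
                n_estimators=RF_N_TREES,
                max_features=min(int(params["mtry"]), X.shape[1]),
                oob_score=True,
                bootstrap=True,
                random_state=seed,
                n_jobs=1,
            )
            est.fit(X, y)
            return float(np.mean((est.oob_prediction_ - y) ** 2))
        folds = KFold(n_splits=min(n_folds, len(y)), shuffle=True, random_state=seed)
        mse = 0.0
        for tr, va in folds.split(X):
            p = dict(params)
            if method == "brt" and "n_trees" not in p:
                p["n_trees"] = _brt_select_n_trees(X[tr], y[tr], p, seed)
            est = _make_estimator(method, p, X.shape[1], seed)
            est.fit(X[tr], y[tr])
            mse += float(np.mean((est.predict(X[va]) - y[va]) ** 2))
        return mse / folds.get_n_splits()

    best = min(
        ((score(c), tuple(c[k] for k in keys), c) for c in combos),
        key=lambda t: (t[0], t[1]),
    )
    return best[2]


# ---------------------------------------------------------------------------
# prediction and ranking


def predict(model: ScoringModel, table: pd.DataFrame) -> np.ndarray:
    """Per-row scores, one per table row, in table order."""
    X = model._matrix(table)
    scores = np.asarray(model.estimator.predict(X), dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ValueError("model produced non-finite scores")
    return scores


def rank_poses(model: ScoringModel, table: pd.DataFrame) -> np.ndarray:
    """0-based row positions ordered best-first.

    RMSD response: ascending predicted score; BA response: descending.
    Ties keep the original row order (stable sort).
    """
    scores = predict(model, table)
    key = scores if model.response == "RMSD" else -scores
    return np.argsort(key, kind="stable")


# ---------------------------------------------------------------------------
# persistence


def save_model(model: ScoringModel, path: str | Path) -> None:
    """Persist a fitted model to a single-file bundle."""
    payload = {
        "format": "poseforge-model",
        "version": 1,
        "model": model,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> ScoringModel:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != "poseforge-model":
        raise ValueError(f"{path}: not a poseforge model bundle")
    return payload["model"]
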