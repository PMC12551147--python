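"""Cross-validated tree-ensemble regression of relative fluorescence.

Random forest (1000 trees, mtry chosen by grid search) or gradient-boosted
trees (XGBoost, small documented grid) are trained on the 157 features with
5-fold cross-validation.  Hyperparameters are selected by minimum pooled
out-of-fold RMSE; model quality is reported as the Pearson correlation and
RMSE between predicted and observed values, per fold and pooled over the
concatenated out-of-fold predictions.  The selected model is refit on all
data for full-space prediction and importance ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from xgboost import XGBRegressor

ALGORITHMS = ("random_forest", "gradient_boosted_trees")

#: mtry grid as fractions of the feature count: sqrt(p), p/3, p/2.
DEFAULT_RF_GRID = (
    {"max_features": "sqrt"},
    {"max_features": 1 / 3},
    {"max_features": 0.5},
)

#: Deliberately small boosting grid; learning rate and depth dominate.
DEFAULT_XGB_GRID = (
    {"learning_rate": 0.1, "max_depth": 3},
    {"learning_rate": 0.1, "max_depth": 5},
    {"learning_rate": 0.3, "max_depth": 3},
    {"learning_rate": 0.3, "max_depth": 5},
)


class SchemaError(ValueError):
    """Prediction-time feature columns do not match the training schema."""


@dataclass(frozen=True)
class ModelConfig:
    algorithm: str = "random_forest"
    n_trees: int = 1000
    grid: Optional[tuple[dict, ...]] = None
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.grid is not None and len(self.grid) == 0:
            raise ValueError("grid must be non-empty")

    @property
    def effective_grid(self) -> tuple[dict, ...]:
        if self.grid is not None:
            return self.grid
        return (
            DEFAULT_RF_GRID
            if self.algorithm == "random_forest"
            else DEFAULT_XGB_GRID
        )


@dataclass
class FoldResult:
    indices: np.ndarray
    predictions: np.ndarray
    pearson_r: float
    rmse: float


@dataclass
class CVResult:
    folds: list[FoldResult]
    oof_predictions: np.ndarray  # aligned with the training rows
    pooled_r: float
    pooled_rmse: float
    r_defined: bool
    best_params: dict
    model: object  # refit on all data
    importance: pd.DataFrame
    feature_names: list[str]
    config: ModelConfig = field(repr=False, default=None)


def evaluate_predictions(pred, obs) -> tuple[float, float]:
    """Pearson r and RMSE between predictions and observations.

    Zero variance in either vector leaves r undefined (NaN); RMSE is always
    valid.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or pred.size < 2:
        raise ValueError("pred and obs must be equal-length vectors (n >= 2)")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return float("nan"), rmse
    r = float(stats.pearsonr(pred, obs).statistic)
    return r, rmse


def _make_estimator(config: ModelConfig, params: dict, seed: int):
    if config.algorithm == "random_forest":
        return RandomForestRegressor(
            n_estimators=config.n_trees,
            random_state=seed,
            n_jobs=1,
            **params,
        )
    defaults = dict(subsample=0.8, colsample_bytree=0.8)
    defaults.update(params)
    return XGBRegressor(
        n_estimators=min(config.n_trees, 300),
        random_state=seed,
        n_jobs=1,
        verbosity=0,
        tree_method="hist",
        **defaults,
    )


def _coerce_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(), list(X.columns)
    X = np.asarray(X)
    return X, [f"f{i}" for i in range(X.shape[1])]


def train_cv(X, y, config: ModelConfig = ModelConfig()) -> CVResult:
    """Grid-searched, cross-validated fit; fully reproducible given the seed.

    For every grid point, out-of-fold predictions are collected over the same
    k-fold split; the point with the lowest pooled RMSE wins (ties keep grid
    order).  Per-fold and pooled metrics are reported for the winner and the
    model is refit on all rows.
    """
    Xm, names = _coerce_matrix(X)
    y = np.asarray(y, dtype=float)
    if Xm.shape[0] != y.size:
        raise ValueError(f"{Xm.shape[0]} rows but {y.size} responses")
    if y.size < config.n_folds:
        raise ValueError("need at least n_folds samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")

    kf = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    splits = list(kf.split(Xm))

    best: tuple[float, int, dict, np.ndarray] | None = None
    for gi, params in enumerate(config.effective_grid):
        oof = np.empty_like(y)
        for train_idx, test_idx in splits:
            est = _make_estimator(config, params, config.seed)
            est.fit(Xm[train_idx], y[train_idx])
            oof[test_idx] = est.predict(Xm[test_idx])
        rmse = float(np.sqrt(np.mean((oof - y) ** 2)))
        if best is None or rmse < best[0]:
            best = (rmse, gi, params, oof)

    pooled_rmse, _, best_params, oof = best
    folds = []
    for train_idx, test_idx in splits:
        r, rmse = (
            evaluate_predictions(oof[test_idx], y[test_idx])
            if test_idx.size >= 2
            else (float("nan"), float(np.sqrt(np.mean((oof[test_idx] - y[test_idx]) ** 2))))
        )
        folds.append(
            FoldResult(indices=test_idx, predictions=oof[test_idx], pearson_r=r, rmse=rmse)
        )
    pooled_r, _ = evaluate_predictions(oof, y)
    r_defined = not math.isnan(pooled_r)

    final = _make_estimator(config, best_params, config.seed)
    # refit on the original container so a DataFrame's column names are
    # recorded for prediction-time schema validation
    final.fit(X if isinstance(X, pd.DataFrame) else Xm, y)
    importance = feature_importance(final, names)

    return CVResult(
        folds=folds,
        oof_predictions=oof,
        pooled_r=pooled_r,
        pooled_rmse=pooled_rmse,
        r_defined=r_defined,
        best_params=dict(best_params),
        model=final,
        importance=importance,
        feature_names=names,
        config=config,
    )


def predict_space(model, X) -> np.ndarray:
    """Score every row of X with a fitted model; deterministic.

    If X is a DataFrame and the model records training column names, a
    mismatch raises :class:`SchemaError` naming the offending columns.
    """
    if isinstance(X, pd.DataFrame):
        trained = getattr(model, "feature_names_in_", None)
        if trained is not None and list(trained) != list(X.columns):
            extra = sorted(set(X.columns) - set(trained))
            missing = sorted(set(trained) - set(X.columns))
            raise SchemaError(
                f"feature columns do not match training schema "
                f"(missing={missing}, unexpected={extra}, or order differs)"
            )
        return np.asarray(model.predict(X))
    return np.asarray(model.predict(np.asarray(X)))


def feature_importance(model, feature_names: Sequence[str]) -> pd.DataFrame:
    """Impurity/gain importances normalized to sum 1, ranked descending.

    Ties break by feature name.  If the model reports all-zero importances
    (degenerate fit on a constant response) the table falls back to uniform
    scores so the sum-to-one invariant holds.
    """
    scores = np.asarray(model.feature_importances_, dtype=float)
    if scores.shape != (len(feature_names),):
        raise ValueError("importance length does not match feature names")
    total = scores.sum()
    scores = scores / total if total > 0 else np.full_like(scores, 1 / scores.size)
    df = pd.DataFrame({"feature": list(feature_names), "importance": scores})
    df = df.sort_values(
        ["importance", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
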