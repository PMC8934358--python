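"""Gradient-boosted regression trees over pair feature matrices.

A thin, deterministic wrapper around XGBoost's squared-error objective
with the handful of knobs that matter for this problem (tree count, depth,
learning rate, row/column subsampling), plus a small grid-search tuner.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from xgboost import XGBRegressor

__all__ = ["BoostParams", "AffinityBoostRegressor", "fit_regressor", "tune"]


@dataclass(frozen=True)
class BoostParams:
    n_trees: int = 500
    max_depth: int = 6
    learning_rate: float = 0.05
    subsample: float = 0.8
    colsample_bytree: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees <= 0 or self.max_depth <= 0 or self.learning_rate <= 0:
            raise ValueError("n_trees, max_depth and learning_rate must be positive")
        if not 0 < self.subsample <= 1 or not 0 < self.colsample_bytree <= 1:
            raise ValueError("subsample and colsample_bytree must lie in (0, 1]")


class AffinityBoostRegressor(BaseEstimator, RegressorMixin):
    """Squared-error XGBoost regressor, single-threaded for determinism.

    ``early_stopping_rounds`` (with ``validation_fraction``) carves a
    validation tail off the training rows and stops adding trees when the
    validation loss stalls.
    """

    def __init__(
        self,
        n_trees: int = 500,
        max_depth: int = 6,
        learning_rate: float = 0.05,
        subsample: float = 0.8,
        colsample_bytree: float = 1.0,
        seed: int = 0,
        early_stopping_rounds: int | None = None,
        validation_fraction: float = 0.1,
    ):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.subsample = subsample
        self.colsample_bytree = colsample_bytree
        self.seed = seed
        self.early_stopping_rounds = early_stopping_rounds
        self.validation_fraction = validation_fraction

    @classmethod
    def from_params(cls, params: BoostParams, **kwargs) -> "AffinityBoostRegressor":
        return cls(
            n_trees=params.n_trees,
            max_depth=params.max_depth,
            learning_rate=params.learning_rate,
            subsample=params.subsample,
            colsample_bytree=params.colsample_bytree,
            seed=params.seed,
            **kwargs,
        )

    def _make_booster(self, early: bool) -> XGBRegressor:
        return XGBRegressor(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            subsample=self.subsample,
            colsample_bytree=self.colsample_bytree,
            objective="reg:squarederror",
            random_state=self.seed,
            n_jobs=1,
            tree_method="hist",
            early_stopping_rounds=self.early_stopping_rounds if early else None,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, p) with one label per row")
        if not np.all(np.isfinite(y)):
            raise ValueError("labels contain NaN or infinity")
        self.n_features_in_ = X.shape[1]
        early = (
            self.early_stopping_rounds is not None
            and 0 < self.validation_fraction < 1
            and X.shape[0] >= 20
        )
        booster = self._make_booster(early)
        if early:
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(X.shape[0])
            n_val = max(1, int(round(self.validation_fraction * X.shape[0])))
            val, trn = order[:n_val], order[n_val:]
            booster.fit(X[trn], y[trn], eval_set=[(X[val], y[val])], verbose=False)
        else:
            booster.fit(X, y)
        self.booster_ = booster
        self.train_mse_ = float(np.mean((booster.predict(X) - y) ** 2))
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "booster_"):
            raise RuntimeError("regressor is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.empty(0)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature count {X.shape[1]} != fitted count {self.n_features_in_}"
            )
        return self.booster_.predict(X)


def fit_regressor(X, y, params: BoostParams = BoostParams(), **kwargs) -> AffinityBoostRegressor:
    return AffinityBoostRegressor.from_params(params, **kwargs).fit(X, y)


def tune(
    X,
    y,
    grid: Sequence[BoostParams],
    folds: int = 5,
    seed: int = 0,
) -> tuple[BoostParams, dict[BoostParams, float]]:
    """Pick the grid point with the lowest mean CV MSE.

    Ties break toward fewer trees, then shallower depth.  Returns the
    winner and the per-point mean CV MSE map.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty parameter grid")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    scores: dict[BoostParams, float] = {}
    for params in grid:
        fold_mse = []
        for trn, val in splits:
            model = AffinityBoostRegressor.from_params(
                params, early_stopping_rounds=None
            ).fit(X[trn], y[trn])
            pred = model.predict(X[val])
            fold_mse.append(np.mean((pred - y[val]) ** 2))
        scores[params] = float(np.mean(fold_mse))
    best = min(grid, key=lambda p: (scores[p], p.n_trees, p.max_depth))
    return best, scores


def default_grid(seed: int = 0) -> list[BoostParams]:
    """A small sensible search space over the tuned knobs."""
    out = []
    for n_trees, depth, lr in itertools.product((200, 500), (4, 6), (0.1, 0.05)):
        out.append(
            BoostParams(
                n_trees=n_trees, max_depth=depth, learning_rate=lr, seed=seed
            )
        )
    return out
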