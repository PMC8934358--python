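"""Evaluation metrics for continuous binding-affinity predictions.

MSE/RMSE, the concordance index with half-credit for tied predictions,
the external-validation statistic rm^2 = r^2 * (1 - sqrt(r^2 - r0^2)),
precision-recall AUC after binarizing at one or more affinity thresholds,
and Y-randomization (label-shuffling) validation.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score

__all__ = [
    "EvalReport",
    "mse",
    "rmse",
    "concordance_index",
    "concordance_index_slow",
    "rm2",
    "PositiveRule",
    "thresholded_aupr",
    "y_randomization",
    "evaluate",
]


class PositiveRule(enum.Enum):
    """Which side of the threshold counts as a binder (positive class)."""

    GE = "ge"  # pKd-style: affinity >= threshold is a binder
    LE = "le"  # raw-distance style: affinity <= threshold is a binder


@dataclass
class EvalReport:
    mse: float
    rmse: float
    ci: float
    r2: float
    r0_2: float
    rm2: float
    aupr_per_threshold: dict[float, float] = field(default_factory=dict)
    aupr_mean: float = float("nan")
    n: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["aupr_per_threshold"] = {str(k): v for k, v in self.aupr_per_threshold.items()}
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _check_pair(pred, actual) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if pred.shape != actual.shape:
        raise ValueError(f"length mismatch: {pred.shape[0]} predictions, {actual.shape[0]} actuals")
    if pred.size == 0:
        raise ValueError("empty vectors")
    return pred, actual


def mse(pred, actual) -> float:
    pred, actual = _check_pair(pred, actual)
    return float(np.mean((pred - actual) ** 2))


def rmse(pred, actual) -> float:
    return float(np.sqrt(mse(pred, actual)))


def concordance_index_slow(pred, actual) -> float:
    """O(n^2) reference: mean of h(pred_x - pred_y) over pairs actual_x > actual_y."""
    pred, actual = _check_pair(pred, actual)
    num = 0.0
    z = 0
    for x in range(len(pred)):
        for y in range(len(pred)):
            if actual[x] > actual[y]:
                z += 1
                d = pred[x] - pred[y]
                num += 1.0 if d > 0 else (0.5 if d == 0 else 0.0)
    if z == 0:
        raise ValueError("all actual values tied; concordance undefined")
    return num / z


class _Fenwick:
    def __init__(self, n: int):
        self.t = np.zeros(n + 1)

    def add(self, i: int, v: float = 1.0) -> None:
        i += 1
        while i < len(self.t):
            self.t[i] += v
            i += i & (-i)

    def prefix(self, i: int) -> float:
        # sum of positions 0..i-1
        s = 0.0
        while i > 0:
            s += self.t[i]
            i -= i & (-i)
        return s


def concordance_index(pred, actual) -> float:
    """Concordance index in O(n log n).

    Processes points in increasing order of ``actual``; within a block of
    tied actuals no pair is counted.  A Fenwick tree over prediction ranks
    counts, for each point, earlier points with smaller / equal prediction
    (h = 1 and h = 0.5 credit respectively).
    """
    pred, actual = _check_pair(pred, actual)
    n = pred.size
    if n < 2 or np.all(actual == actual[0]):
        raise ValueError("need at least two distinct actual values")
    pred_rank = stats.rankdata(pred, method="dense").astype(int) - 1
    n_ranks = pred_rank.max() + 1
    order = np.argsort(actual, kind="stable")
    tree = _Fenwick(n_ranks)
    seen = 0
    num = 0.0
    z = 0
    i = 0
    while i < n:
        j = i
        while j < n and actual[order[j]] == actual[order[i]]:
            j += 1
        block = order[i:j]
        for idx in block:
            r = pred_rank[idx]
            below = tree.prefix(r)
            at = tree.prefix(r + 1) - below
            num += below + 0.5 * at
            z += seen
        for idx in block:
            tree.add(pred_rank[idx])
        seen += len(block)
        i = j
    return num / z


def rm2(pred, actual, origin_axis: str = "actual_on_pred") -> tuple[float, float, float]:
    """(r^2, r0^2, rm^2) with rm^2 = r^2 * (1 - sqrt(max(r^2 - r0^2, 0))).

    r^2 is the squared Pearson correlation; r0^2 is the determination
    coefficient of the least-squares regression through the origin, by
    default of the actual values on the predictions
    (k = sum(y*p)/sum(p^2), r0^2 = 1 - sum((y - k p)^2)/sum((y - ybar)^2));
    ``origin_axis="pred_on_actual"`` swaps the roles.
    """
    pred, actual = _check_pair(pred, actual)
    if pred.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(pred) == 0 or np.std(actual) == 0:
        raise ValueError("zero variance in predictions or actuals")
    r = np.corrcoef(pred, actual)[0, 1]
    r2 = float(r * r)
    if origin_axis == "actual_on_pred":
        y, x = actual, pred
    elif origin_axis == "pred_on_actual":
        y, x = pred, actual
    else:
        raise ValueError(f"unknown origin_axis {origin_axis!r}")
    k = float(np.sum(y * x) / np.sum(x * x))
    ss_res = float(np.sum((y - k * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r0_2 = 1.0 - ss_res / ss_tot
    rad = max(r2 - r0_2, 0.0)
    rm_2 = r2 * (1.0 - np.sqrt(rad))
    return r2, float(r0_2), float(rm_2)


def thresholded_aupr(
    pred,
    actual,
    thresholds: Sequence[float],
    positive_rule: PositiveRule = PositiveRule.GE,
) -> tuple[dict[float, float], float]:
    """Binarize actuals at each threshold and compute precision-recall AUC.

    Prediction scores are oriented so that larger score = more likely
    positive (negated when the positive rule is LE).  Thresholds where
    only one class exists are reported as NaN and excluded from the mean.
    """
    pred, actual = _check_pair(pred, actual)
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("no thresholds given")
    scores = pred if positive_rule is PositiveRule.GE else -pred
    per: dict[float, float] = {}
    defined = []
    for t in thresholds:
        labels = (actual >= t) if positive_rule is PositiveRule.GE else (actual <= t)
        if labels.all() or not labels.any():
            warnings.warn(f"threshold {t}: single-class labels, AUPR undefined")
            per[t] = float("nan")
            continue
        val = float(average_precision_score(labels.astype(int), scores))
        per[t] = val
        defined.append(val)
    mean = float(np.mean(defined)) if defined else float("nan")
    return per, mean


def y_randomization(
    X_train,
    y_train,
    X_test,
    y_test,
    model_factory,
    n_iter: int = 100,
    seed: int = 0,
) -> dict:
    """Label-shuffling validation on a held-out test split.

    Fits ``model_factory()`` on the true training labels and on ``n_iter``
    shuffled copies, scoring each by r^2 (coefficient of determination) on
    the test set.  Reports a parametric p-value from a normal fit to the
    permuted r^2 distribution and the empirical rank p-value
    (count(perm >= observed) + 1) / (n_iter + 1).
    """
    if n_iter < 10:
        raise ValueError("n_iter must be >= 10")
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    rng = np.random.default_rng(seed)

    def _r2(model) -> float:
        pred = model.predict(X_test)
        ss_res = float(np.sum((y_test - pred) ** 2))
        ss_tot = float(np.sum((y_test - y_test.mean()) ** 2))
        return 1.0 - ss_res / ss_tot

    observed = _r2(model_factory().fit(X_train, y_train))
    permuted = []
    for _ in range(n_iter):
        y_perm = rng.permutation(y_train)
        permuted.append(_r2(model_factory().fit(X_train, y_perm)))
    permuted_arr = np.array(permuted)
    mu, sd = permuted_arr.mean(), permuted_arr.std(ddof=1)
    p_normal = float(stats.norm.sf(observed, loc=mu, scale=sd)) if sd > 0 else (
        0.0 if observed > mu else 1.0
    )
    p_empirical = (int(np.sum(permuted_arr >= observed)) + 1) / (n_iter + 1)
    return {
        "observed_r2": float(observed),
        "permuted_r2": permuted,
        "p_value_normal": p_normal,
        "p_value_empirical": float(p_empirical),
    }


def evaluate(
    pred,
    actual,
    thresholds: Sequence[float] = (),
    positive_rule: PositiveRule = PositiveRule.GE,
) -> EvalReport:
    """Full metric suite on one prediction vector."""
    pred, actual = _check_pair(pred, actual)
    m = mse(pred, actual)
    r2, r0_2, rm_2 = rm2(pred, actual)
    per, mean_aupr = thresholded_aupr(pred, actual, thresholds, positive_rule) if thresholds else ({}, float("nan"))
    return EvalReport(
        mse=m,
        rmse=float(np.sqrt(m)),
        ci=concordance_index(pred, actual),
        r2=r2,
        r0_2=r0_2,
        rm2=rm_2,
        aupr_per_threshold=per,
        aupr_mean=mean_aupr,
        n=int(pred.size),
    )
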