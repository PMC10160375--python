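"""Random-forest grid search, out-of-bag noise-injection importance and
backward feature elimination.

The forest is a bagged ensemble of CART trees (scikit-learn supplies the
trees; bootstrap bookkeeping is explicit so every tree's out-of-bag set is
known).  The ensemble prediction is the majority vote H(X) over the k
trees.  Feature importance follows the out-of-bag noise-injection form

    importance_j = sum_trees (errOOB2 - errOOB1) / Ntree,

where errOOB1 is a tree's OOB error and errOOB2 its OOB error after the
j-th feature's OOB values are permuted ("adding noise").  Backward
elimination repeatedly drops the lowest-importance feature and scores each
retained set with a normalized error

    RMSE = sqrt( sum (y_obs - y_pred)² / sum (y_obs - mean(y_pred))² )

evaluated on out-of-fold predictions, plus a relative error RE (mean
absolute error over the observed-label range).  The retained feature count
is the RMSE-minimizing point of the trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

log = logging.getLogger(__name__)


@dataclass
class ForestSpec:
    """Hyperparameters of the bagged-tree ensemble."""

    n_estimators: int = 11
    max_depth: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1 or self.max_depth < 1:
            raise ValueError("n_estimators and max_depth must be >= 1")


class BaggedForest:
    """Bagged CART ensemble with explicit bootstrap/out-of-bag bookkeeping."""

    def __init__(self, spec: ForestSpec):
        self.spec = spec
        self.trees_: list[DecisionTreeClassifier] = []
        self.oob_indices_: list[np.ndarray] = []
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training labels contain a single class")
        n = X.shape[0]
        rng = np.random.default_rng(self.spec.seed)
        self.trees_, self.oob_indices_ = [], []
        for _ in range(self.spec.n_estimators):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            tree = DecisionTreeClassifier(
                max_depth=self.spec.max_depth,
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(X[boot], y[boot])
            self.trees_.append(tree)
            self.oob_indices_.append(oob)
        return self

    def _votes(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting for the positive (last) class."""
        pos = self.classes_[-1]
        votes = np.zeros(X.shape[0])
        for tree in self.trees_:
            votes += tree.predict(X) == pos
        return votes / len(self.trees_)

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """Positive-class vote fraction in [0, 1] (ranking score)."""
        return self._votes(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Majority-vote labels; exact ties go to the negative class."""
        scores = self.predict_score(X)
        return np.where(scores > 0.5, self.classes_[-1], self.classes_[0])

def _tree_oob_error(tree: DecisionTreeClassifier, X_oob: np.ndarray, y_oob: np.ndarray) -> float:
    return float(np.mean(tree.predict(X_oob) != y_oob))


def oob_importance(
    spec: ForestSpec,
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    seed: int | None = None,
    forest: BaggedForest | None = None,
) -> pd.Series:
    """Out-of-bag noise-injection importance per feature, descending.

    For each feature the OOB values are permuted within each tree's OOB
    set and the mean per-tree error increase recorded.  Trees with an
    empty OOB set are skipped and the tree count adjusted.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{j}" for j in range(np.asarray(X).shape[1])
    ]
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if forest is None:
        forest = BaggedForest(spec).fit(Xa, y)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sums = np.zeros(len(names))
    n_used = 0
    for tree, oob in zip(forest.trees_, forest.oob_indices_):
        if oob.size == 0:
            continue
        n_used += 1
        X_oob, y_oob = Xa[oob], y[oob]
        err1 = _tree_oob_error(tree, X_oob, y_oob)
        for j in range(len(names)):
            perm = rng.permutation(oob.size)
            X_perm = X_oob.copy()
            X_perm[:, j] = X_oob[perm, j]
            sums[j] += _tree_oob_error(tree, X_perm, y_oob) - err1
    if n_used == 0:
        raise ValueError("no tree has a non-empty out-of-bag set")
    imp = pd.Series(sums / n_used, index=names, name="importance")
    return imp.sort_values(ascending=False, kind="stable")


def rf_grid_search(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    n_estimators_grid: tuple[int, ...] = (5, 10, 15, 20, 30, 50),
    max_depth_grid: tuple[int, ...] = (2, 4, 6, 8, 10, 15, 20),
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[ForestSpec, pd.DataFrame]:
    """Cross-validated accuracy over the (n_estimators, max_depth) grid.

    Returns the best spec (ties broken toward the smaller ensemble, then
    the shallower depth) and the full score surface for reporting.
    """
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("grid search needs both classes present")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(Xa, y))
    rows = []
    best: tuple[float, int, int] | None = None
    for ne in n_estimators_grid:
        for md in max_depth_grid:
            accs = []
            for f, (tr, te) in enumerate(folds):
                forest = BaggedForest(ForestSpec(ne, md, seed=seed * 1000 + f)).fit(
                    Xa[tr], y[tr]
                )
                accs.append(float(np.mean(forest.predict(Xa[te]) == y[te])))
            score = float(np.mean(accs))
            rows.append({"n_estimators": ne, "max_depth": md, "cv_accuracy": score})
            key = (score, -ne, -md)
            if best is None or key > (best[0], -best[1], -best[2]):
                best = (score, ne, md)
    surface = pd.DataFrame(rows)
    assert best is not None
    return ForestSpec(best[1], best[2], seed=seed), surface


def normalized_rmse(y_obs: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """The normalized RMSE and relative error used by the elimination trace.

    RMSE = sqrt( Σ(y_obs − y_pred)² / Σ(y_obs − mean(y_pred))² ); the
    denominator is the spread of the observations around the *prediction*
    mean, making the statistic scale-free and shift-invariant.  RE is the
    mean absolute error divided by the observed-label range (= plain MAE
    for 0/1 labels).
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.size < 2:
        raise ValueError("normalized_rmse needs two equal-length vectors, n >= 2")
    den = float(np.sum((y_obs - y_pred.mean()) ** 2))
    if den == 0:
        raise ValueError("degenerate denominator: observations equal the prediction mean")
    rmse = float(np.sqrt(np.sum((y_obs - y_pred) ** 2) / den))
    rng_obs = float(y_obs.max() - y_obs.min())
    re = float(np.mean(np.abs(y_obs - y_pred))) / (rng_obs if rng_obs > 0 else 1.0)
    return rmse, re


def conventional_rmse(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Ordinary root-mean-square error (reference only; never drives
    elimination)."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))


def _cv_errors(
    X: np.ndarray, y: np.ndarray, spec: ForestSpec, cv_folds: int, seed: int
) -> tuple[float, float]:
    """Out-of-fold normalized_rmse/RE for a feature set."""
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(np.asarray(y, dtype=float))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        forest = BaggedForest(
            ForestSpec(spec.n_estimators, spec.max_depth, seed=seed * 997 + f)
        ).fit(X[tr], y[tr])
        y_pred[te] = forest.predict(X[te]).astype(float)
    return normalized_rmse(np.asarray(y, dtype=float), y_pred)


@dataclass
class EliminationTrace:
    """Backward-elimination record: one row per retained-feature count."""

    trace: pd.DataFrame = field(default_factory=pd.DataFrame)
    best_count: int = 0
    best_features: list[str] = field(default_factory=list)
    importance_initial: pd.Series | None = None


def backward_eliminate(
    X: pd.DataFrame,
    y: np.ndarray,
    spec: ForestSpec,
    seed: int = 0,
    cv_folds: int = 5,
) -> EliminationTrace:
    """Iteratively drop the lowest-importance feature and score the rest.

    Starting from p features the trace holds p−1 entries (counts p−1 .. 1),
    each with the retained set and its out-of-fold (RMSE, RE).  Ties in the
    lowest importance are broken by dropping the lexicographically last
    name (logged).  The retained set is the RMSE-minimizing count (ties ->
    the larger count).
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("backward elimination needs >= 2 features")
    y = np.asarray(y)
    features = list(X.columns)
    imp0 = oob_importance(spec, X, y, seed=seed)
    rows = []
    sets: dict[int, list[str]] = {}
    current = list(features)
    imp = imp0
    step = 0
    while len(current) > 1:
        lowest = imp.min()
        candidates = sorted(imp.index[np.isclose(imp.values, lowest)])
        drop = candidates[-1]
        if len(candidates) > 1:
            log.info("importance tie among %s; dropping %r", candidates, drop)
        current = [f for f in current if f != drop]
        step += 1
        rmse, re = _cv_errors(
            X[current].to_numpy(), y, spec, cv_folds, seed=seed + step
        )
        rows.append(
            {"n_features": len(current), "rmse": rmse, "re": re, "dropped": drop}
        )
        sets[len(current)] = list(current)
        if len(current) > 1:
            imp = oob_importance(spec, X[current], y, seed=seed + 7919 * step)
    trace = pd.DataFrame(rows)
    best_idx = trace["rmse"].idxmin()  # first occurrence = largest count
    best_count = int(trace.loc[best_idx, "n_features"])
    return EliminationTrace(
        trace=trace,
        best_count=best_count,
        best_features=sets[best_count],
        importance_initial=imp0,
    )
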