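"""Supervised cell-type classifiers with tuning and feature selection.

Four model families are compared under repeated stratified k-fold cross
validation with ROC-AUC as the optimization metric: multivariate logistic
regression, boosted decision trees (XGBoost), a support-vector classifier
and k-nearest neighbors.  Hyperparameter search is either exhaustive
("grid") or a seeded random sample of the space ("sampled") with an
optional median-rule pruner that abandons a trial whose partial mean falls
below the median of earlier trials at the same fold checkpoint.

The boosted-tree model additionally exposes gain-based feature importances
(normalized to sum to 1), which drive importance-cutoff feature selection:
retrain on the top-m features for a list of cutoffs and keep the subset
with the best cross-validated score, breaking ties toward fewer features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (ParameterGrid, ParameterSampler,
                                     RepeatedStratifiedKFold)
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

logger = logging.getLogger(__name__)

__all__ = ["ModelSpec", "CVSpec", "SearchSpec", "ImportanceRanking",
           "CVReport", "cross_validate", "importance_ranking",
           "feature_cutoff_sweep", "predict", "encode_labels",
           "DEFAULT_SPACES", "POSITIVE_LABEL"]

POSITIVE_LABEL = "beta"

MODEL_FAMILIES = ("logistic-regression", "boosted-trees",
                  "support-vector", "k-nearest-neighbor")

#: compact default hyperparameter spaces per family (declared config; the
#: sampled strategy draws uniformly from the same grids)
DEFAULT_SPACES: dict[str, dict[str, list]] = {
    "logistic-regression": {"C": [0.1, 1.0, 10.0]},
    "boosted-trees": {
        "n_estimators": [50, 100],
        "max_depth": [3, 4, 6],
        "learning_rate": [0.05, 0.1, 0.3],
        "subsample": [0.8, 1.0],
        "colsample_bytree": [0.8, 1.0],
    },
    "support-vector": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.1]},
    "k-nearest-neighbor": {"n_neighbors": [3, 5, 9, 15]},
}


@dataclass
class ModelSpec:
    family: str
    space: dict[str, list] = field(default_factory=dict)
    class_weight_balanced: bool = False

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if not self.space:
            self.space = DEFAULT_SPACES[self.family]

    def build(self, params: dict, seed: int = 0):
        cw = "balanced" if self.class_weight_balanced else None
        if self.family == "logistic-regression":
            return LogisticRegression(max_iter=2000, class_weight=cw, **params)
        if self.family == "boosted-trees":
            return XGBClassifier(tree_method="hist", n_jobs=1,
                                 eval_metric="logloss", random_state=seed,
                                 **params)
        if self.family == "support-vector":
            return SVC(probability=True, class_weight=cw, random_state=seed,
                       **params)
        return KNeighborsClassifier(**params)


@dataclass
class CVSpec:
    n_folds: int = 5
    n_repeats: int = 3
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")

    def splitter(self) -> RepeatedStratifiedKFold:
        return RepeatedStratifiedKFold(n_splits=self.n_folds,
                                       n_repeats=self.n_repeats,
                                       random_state=self.seed)


@dataclass
class SearchSpec:
    strategy: str = "sampled"       # "grid" | "sampled"
    budget: int = 50                # trials (sampled strategy)
    objective: str = "roc_auc"
    pruning: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("grid", "sampled"):
            raise ValueError(f"unknown search strategy {self.strategy!r}")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")

    def candidates(self, space: dict[str, list]) -> list[dict]:
        if self.strategy == "grid":
            return list(ParameterGrid(space))
        n_grid = int(np.prod([len(v) for v in space.values()]))
        n = min(self.budget, n_grid)
        return list(ParameterSampler(space, n_iter=n,
                                     random_state=self.seed))


@dataclass
class ImportanceRanking:
    """Feature importances sorted from most to least relevant; sum to 1."""

    pairs: list[tuple[str, float]]

    def __post_init__(self) -> None:
        scores = np.array([s for _, s in self.pairs])
        if np.any(scores < 0):
            raise ValueError("importance scores must be non-negative")
        if scores.size and abs(scores.sum() - 1.0) > 1e-6:
            raise ValueError("importance scores must sum to 1")
        if np.any(np.diff(scores) > 1e-12):
            raise ValueError("scores must be non-increasing")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.pairs]

    def top(self, m: int) -> list[str]:
        return self.names[:m]


@dataclass
class CVReport:
    trials: pd.DataFrame            # params, per-fold scores, mean, sd
    best_params: dict
    best_mean: float
    best_sd: float
    cv: CVSpec
    search: SearchSpec


def encode_labels(y: pd.Series | np.ndarray,
                  positive: str = POSITIVE_LABEL) -> np.ndarray:
    """Map string labels to {0, 1} with the positive (beta) class as 1."""
    arr = np.asarray(y)
    if arr.dtype.kind in "iufb":
        return arr.astype(int)
    return (arr == positive).astype(int)


def _fold_scores(model, X: np.ndarray, y: np.ndarray, cv: CVSpec,
                 prune_refs: list[list[float]] | None = None) -> np.ndarray | None:
    """Per-fold ROC-AUC; returns None when the trial is pruned."""
    scores: list[float] = []
    for i, (tr, te) in enumerate(cv.splitter().split(X, y)):
        if y[tr].min() == y[tr].max() or y[te].min() == y[te].max():
            raise RuntimeError("a CV fold lacks one of the classes")
        m = model.fit(X[tr], y[tr])
        if hasattr(m, "predict_proba"):
            s = m.predict_proba(X[te])[:, 1]
        else:
            s = m.decision_function(X[te])
        scores.append(float(roc_auc_score(y[te], s)))
        if prune_refs is not None and len(prune_refs) >= 3:
            partial = float(np.mean(scores))
            ref = np.median([np.mean(r[:i + 1]) for r in prune_refs
                             if len(r) > i])
            if partial < ref - 1e-12 and i + 1 < cv.n_folds * cv.n_repeats:
                logger.debug("pruned after %d folds (%.4f < %.4f)",
                             i + 1, partial, ref)
                return None
    return np.asarray(scores)


def cross_validate(X: pd.DataFrame, y: pd.Series, model: ModelSpec,
                   cv: CVSpec | None = None,
                   search: SearchSpec | None = None):
    """Tune a model family by repeated stratified CV; refit the best.

    Returns ``(best_model, CVReport)`` where the best model is refit on the
    full training partition with the best hyperparameters.
    """
    cv = cv or CVSpec()
    search = search or SearchSpec()
    Xa = np.asarray(X, dtype=float)
    ya = encode_labels(y)
    rows = []
    completed: list[list[float]] = []
    for t, params in enumerate(search.candidates(model.space)):
        est = model.build(params, seed=search.seed)
        scores = _fold_scores(est, Xa, ya, cv,
                              prune_refs=completed if search.pruning else None)
        if scores is None:
            rows.append({"params": params, "mean": np.nan, "sd": np.nan,
                         "pruned": True, "scores": None})
            continue
        completed.append(list(scores))
        rows.append({"params": params, "mean": float(scores.mean()),
                     "sd": float(scores.std()), "pruned": False,
                     "scores": scores})
    trials = pd.DataFrame(rows)
    valid = trials.dropna(subset=["mean"])
    best_i = int(valid["mean"].idxmax())
    best_params = trials.loc[best_i, "params"]
    best_model = model.build(best_params, seed=search.seed)
    if isinstance(X, pd.DataFrame):
        best_model.fit(X, ya)
    else:
        best_model.fit(Xa, ya)
    report = CVReport(trials=trials, best_params=best_params,
                      best_mean=float(trials.loc[best_i, "mean"]),
                      best_sd=float(trials.loc[best_i, "sd"]),
                      cv=cv, search=search)
    return best_model, report


def importance_ranking(model, feature_names: list[str] | None = None,
                       ) -> ImportanceRanking:
    """Normalized gain-based importance ranking of a fitted boosted-tree model."""
    if not isinstance(model, XGBClassifier):
        raise TypeError("importance ranking is defined for the boosted-tree "
                        "family only")
    scores = np.asarray(model.feature_importances_, dtype=float)
    if feature_names is None:
        feature_names = model.get_booster().feature_names
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(scores.size)]
    total = scores.sum()
    if total > 0:
        scores = scores / total
    order = np.argsort(-scores, kind="stable")
    return ImportanceRanking([(feature_names[i], float(scores[i]))
                              for i in order])


def feature_cutoff_sweep(X: pd.DataFrame, y: pd.Series,
                         ranking: ImportanceRanking,
                         cutoffs: list[int], model: ModelSpec,
                         cv: CVSpec | None = None,
                         search: SearchSpec | None = None):
    """Retrain at each importance cutoff and pick the best feature subset.

    Ties in mean CV score resolve toward the smaller feature count, then
    the lower cutoff index.  Returns ``(sweep_table, best_subset,
    best_model, best_report)``.
    """
    if max(cutoffs) > X.shape[1]:
        raise ValueError("cutoff exceeds the number of features")
    rows = []
    results = {}
    for m in cutoffs:
        subset = ranking.top(m)
        mdl, rep = cross_validate(X[subset], y, model, cv=cv, search=search)
        rows.append({"cutoff": m, "mean": rep.best_mean, "sd": rep.best_sd,
                     "params": rep.best_params})
        results[m] = (mdl, rep)
    table = pd.DataFrame(rows)
    best_row = table.sort_values(["mean", "cutoff"],
                                 ascending=[False, True]).iloc[0]
    best_m = int(best_row["cutoff"])
    best_model, best_report = results[best_m]
    return table, ranking.top(best_m), best_model, best_report


def predict(model, X: pd.DataFrame, threshold: float = 0.5,
            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-row probability of the beta class and thresholded labels."""
    proba = model.predict_proba(X)[:, 1]
    return proba, (proba >= threshold).astype(int)
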