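"""Held-out evaluation and the stability battery.

Beyond the held-out metrics report, three controls probe the robustness of
the trained classifier: (i) a tenfold cross-validation variant re-runs the
whole tuning at 10 folds and compares the CV means, (ii) the Salzberg
test retrains the identical pipeline on label-shuffled training data —
near-chance performance certifies that the pipeline cannot learn from
noise (no leakage, no overfitting of the tuning loop), and (iii) the
records excluded by manual cleaning are classified with the final model,
where degraded metrics indicate the exclusions carried label noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score

from .classify import (CVSpec, ModelSpec, SearchSpec, cross_validate,
                       encode_labels, predict)

logger = logging.getLogger(__name__)

__all__ = ["MetricsReport", "evaluate", "salzberg_test",
           "classify_excluded", "tenfold_variant"]


@dataclass
class MetricsReport:
    """Class-wise held-out metrics at a fixed decision threshold.

    Metrics with a zero denominator are reported as NaN (missing), never
    silently as 0.  Class-wise precision/recall follow the convention of
    reporting beta and alpha separately rather than averaged.
    """

    roc_auc: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    accuracy: float
    n_test: int
    confusion: dict[str, int] = field(default_factory=dict)  # tp/fp/fn/tn

    def as_dict(self) -> dict:
        return {"roc_auc": self.roc_auc, "precision": self.precision,
                "recall": self.recall, "f1": self.f1,
                "accuracy": self.accuracy, "n_test": self.n_test,
                "confusion": self.confusion}


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int,
                           roc_auc: float = float("nan")) -> MetricsReport:
    """Definitional class-wise metrics from confusion counts.

    The beta class is the positive one; alpha metrics are the complements
    (tn/fn swap roles).  F1 is the harmonic mean of precision and recall.
    """
    prec = {"beta": _safe_div(tp, tp + fp), "alpha": _safe_div(tn, tn + fn)}
    rec = {"beta": _safe_div(tp, tp + fn), "alpha": _safe_div(tn, tn + fp)}
    f1 = {}
    for c in ("beta", "alpha"):
        p, r = prec[c], rec[c]
        f1[c] = _safe_div(2 * p * r, p + r) if np.isfinite(p + r) else float("nan")
    n = tp + fp + fn + tn
    return MetricsReport(
        roc_auc=roc_auc, precision=prec, recall=rec, f1=f1,
        accuracy=_safe_div(tp + tn, n), n_test=n,
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn})


def evaluate(model, X_test: pd.DataFrame, y_test: pd.Series,
             threshold: float = 0.5) -> MetricsReport:
    """Score a fitted model on held-out data (transformed by the training
    state).  A single-class test set leaves ROC-AUC missing, flagged."""
    y = encode_labels(y_test)
    proba, pred = predict(model, X_test, threshold=threshold)
    if y.min() == y.max():
        logger.warning("evaluate: single-class test set, ROC-AUC undefined")
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y, proba))
    tn, fp, fn, tp = confusion_matrix(y, pred, labels=[0, 1]).ravel()
    return metrics_from_confusion(int(tp), int(fp), int(fn), int(tn),
                                  roc_auc=auc)


@dataclass
class SalzbergReport:
    shuffled: MetricsReport
    shuffled_train: MetricsReport
    real: MetricsReport
    relative_drop_test: float
    relative_drop_train: float


def salzberg_test(X_train: pd.DataFrame, y_train: pd.Series,
                  X_test: pd.DataFrame, y_test: pd.Series,
                  model: ModelSpec, cv: CVSpec | None = None,
                  search: SearchSpec | None = None,
                  seed: int = 0,
                  real_report: MetricsReport | None = None,
                  real_model=None,
                  permutation: np.ndarray | None = None) -> SalzbergReport:
    """Retrain the identical pipeline on label-shuffled training data.

    The permutation is seeded; the identity permutation (e.g. from an
    already-sorted draw) reproduces the real run exactly, since everything
    else is shared.  Reports shuffled train and test metrics alongside the
    real run's and the relative ROC-AUC drops.
    """
    if permutation is None:
        permutation = np.random.default_rng(seed).permutation(len(y_train))
    perm = np.asarray(permutation)
    y_shuf = pd.Series(np.asarray(y_train)[perm], index=y_train.index,
                       name=y_train.name)
    if real_model is None:
        real_model, _ = cross_validate(X_train, y_train, model, cv=cv,
                                       search=search)
    if real_report is None:
        real_report = evaluate(real_model, X_test, y_test)
    shuf_model, _ = cross_validate(X_train, y_shuf, model, cv=cv,
                                   search=search)
    shuffled = evaluate(shuf_model, X_test, y_test)
    shuffled_train = evaluate(shuf_model, X_train, y_shuf)
    drop_test = ((real_report.roc_auc - shuffled.roc_auc)
                 / real_report.roc_auc if real_report.roc_auc else float("nan"))
    real_train = evaluate(real_model, X_train, y_train)
    drop_train = ((real_train.roc_auc - shuffled_train.roc_auc)
                  / real_train.roc_auc if real_train.roc_auc else float("nan"))
    return SalzbergReport(shuffled=shuffled, shuffled_train=shuffled_train,
                          real=real_report,
                          relative_drop_test=float(drop_test),
                          relative_drop_train=float(drop_train))


def classify_excluded(model, X_excluded: pd.DataFrame,
                      y_excluded: pd.Series,
                      threshold: float = 0.5) -> MetricsReport | None:
    """Score the cleaning-excluded records with the final model.

    Returns None for an empty excluded partition.  When exclusion
    correlates with label noise these metrics fall below the clean-test
    report, validating the cleaning procedure.
    """
    if len(X_excluded) == 0:
        logger.info("classify_excluded: empty excluded partition")
        return None
    return evaluate(model, X_excluded, y_excluded, threshold=threshold)


def tenfold_variant(X_train: pd.DataFrame, y_train: pd.Series,
                    model: ModelSpec, search: SearchSpec | None = None,
                    seed: int = 0, base_folds: int = 5,
                    n_repeats: int = 3) -> pd.DataFrame:
    """Re-run the full optimization at 10 folds and compare CV means.

    Returns a two-row table (5-fold and 10-fold CV means and sds) plus the
    absolute difference as a table attribute.
    """
    rows = []
    for folds in (base_folds, 10):
        cv = CVSpec(n_folds=folds, n_repeats=n_repeats, seed=seed)
        _, rep = cross_validate(X_train, y_train, model, cv=cv,
                                search=search)
        rows.append({"n_folds": folds, "cv_mean": rep.best_mean,
                     "cv_sd": rep.best_sd, "best_params": rep.best_params})
    table = pd.DataFrame(rows)
    table.attrs["abs_difference"] = float(
        abs(table.loc[0, "cv_mean"] - table.loc[1, "cv_mean"]))
    return table
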