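"""Cleaning and preprocessing chain for the single-cell feature matrix.

Frozen stage order: clean -> encode -> impute -> outliers -> scale ->
split -> SMOTE (training partition only).  All fitted statistics (feature
minima/maxima for scaling, inlier feature means for outlier substitution)
come from the training partition alone, so no test row influences any
fitted quantity; a ``pool_before_split`` mode instead fits on the whole
dataset before splitting, for replication of analyses that rebalance
the pooled dataset.

Missing values are imputed with zeros: they encode the physical absence of
NAD(P)H or lipofuscin signal, not an unknown measurement.  SMOTE synthetic
minority rows are convex combinations ``x + u (x_nn - x)``, ``u ~ U(0,1)``,
between a minority point and one of its k nearest minority neighbors.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.neighbors import LocalOutlierFactor, NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = ["CleaningManifest", "PreprocessState", "clean",
           "encode_categoricals", "impute_missing", "replace_outliers",
           "scale_minmax", "split_stratified", "rebalance_smote",
           "run_preprocessing", "PreprocessedData"]

EXCLUSION_REASONS = frozenset({
    "ambiguous-identity", "rearrangement", "focal-plane-mismatch",
    "shape-change", "duplicate",
})


@dataclass
class CleaningManifest:
    """Reason-coded list of excluded cell ids (the manual-review audit)."""

    exclusions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.exclusions.values()) - EXCLUSION_REASONS
        if bad:
            raise ValueError(f"unknown exclusion reason codes: {sorted(bad)}")

    @property
    def excluded_ids(self) -> set[str]:
        return set(self.exclusions)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.exclusions, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CleaningManifest":
        return cls(json.loads(Path(path).read_text()))


def _cell_ids(matrix: pd.DataFrame) -> np.ndarray:
    if "cell_id" in (matrix.index.names or []):
        return matrix.index.get_level_values("cell_id").to_numpy()
    return matrix.index.to_numpy()


def clean(matrix: pd.DataFrame, target: pd.Series,
          manifest: CleaningManifest,
          ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.Series]:
    """Partition rows into retained and excluded sets by the manifest.

    All rows of an excluded cell (both glucose conditions) are removed.
    Exact duplicate feature rows among the retained set are dropped.  The
    excluded partition is returned for the stability battery, which
    classifies it with the final model.
    """
    ids = _cell_ids(matrix)
    unknown = manifest.excluded_ids - set(ids)
    if unknown:
        raise ValueError(f"manifest lists unknown cell ids: {sorted(unknown)[:5]}")
    excl = np.isin(ids, list(manifest.excluded_ids))
    retained_m, retained_y = matrix.loc[~excl], target.loc[~excl]
    excluded_m, excluded_y = matrix.loc[excl], target.loc[excl]
    dup = retained_m.duplicated(keep="first")
    if dup.any():
        logger.warning("clean: dropping %d duplicate rows", int(dup.sum()))
        retained_m, retained_y = retained_m.loc[~dup], retained_y.loc[~dup]
    return retained_m, retained_y, excluded_m, excluded_y


def encode_categoricals(matrix: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode any non-numeric columns (e.g. a donor-id column).

    The standard 151-feature schema is already numeric (glucose condition
    is encoded 0/1 at matrix assembly), in which case this is a no-op.
    """
    obj_cols = [c for c in matrix.columns
                if not pd.api.types.is_numeric_dtype(matrix[c])]
    if not obj_cols:
        return matrix
    return pd.get_dummies(matrix, columns=obj_cols, dtype=float)


def impute_missing(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace every missing value with 0 (absence of signal); nothing else."""
    return matrix.fillna(0.0)


def replace_outliers(matrix: pd.DataFrame, n_neighbors: int = 20,
                     contamination: str | float = "auto",
                     ) -> tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """Replace rows flagged by the local outlier factor with feature means.

    LOF flags whole rows; every feature of a flagged row is substituted by
    the feature's mean over the inlier rows.  Returns the cleaned matrix,
    the boolean outlier flags and the inlier means (reused to substitute
    outliers in unseen data).  With fewer than ``n_neighbors + 1`` rows the
    step is skipped with a warning.
    """
    if matrix.shape[0] < n_neighbors + 1:
        warnings.warn("replace_outliers: too few rows, step skipped")
        means = matrix.mean(axis=0)
        return matrix, np.zeros(matrix.shape[0], dtype=bool), means
    lof = LocalOutlierFactor(n_neighbors=n_neighbors,
                             contamination=contamination)
    flags = lof.fit_predict(matrix.to_numpy()) == -1
    means = matrix.loc[~flags].mean(axis=0)
    out = matrix.copy()
    out.loc[flags, :] = means.to_numpy()
    return out, flags, means


@dataclass
class PreprocessState:
    """Statistics fitted on the training partition only.

    Applying the state is idempotent: a matrix already transformed by this
    state is returned unchanged (tracked through a frame attribute).
    """

    feature_min: pd.Series
    feature_max: pd.Series
    inlier_means: pd.Series
    columns: list[str]
    fitted_on: str = "train"

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        if matrix.attrs.get("minmax_state") is self:
            return matrix
        if list(matrix.columns) != self.columns:
            raise ValueError("matrix columns do not match the fitted state")
        rng = self.feature_max - self.feature_min
        safe = rng.replace(0.0, 1.0)
        out = (matrix - self.feature_min) / safe
        out.loc[:, rng == 0.0] = 0.0
        out.attrs["minmax_state"] = self
        return out


def scale_minmax(matrix: pd.DataFrame,
                 state: PreprocessState | None = None,
                 ) -> tuple[pd.DataFrame, PreprocessState]:
    """Min-max scale features: training min -> 0, training max -> 1.

    A constant feature maps to 0 by convention.  Values of unseen data may
    fall outside [0, 1]; they are not clipped.
    """
    if state is None:
        state = PreprocessState(
            feature_min=matrix.min(axis=0), feature_max=matrix.max(axis=0),
            inlier_means=matrix.mean(axis=0), columns=list(matrix.columns))
    return state.transform(matrix), state


def split_stratified(matrix: pd.DataFrame, target: pd.Series,
                     test_fraction: float = 0.25, seed: int = 0,
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Seeded stratified train/test split preserving class proportions.

    When the row index carries a ``cell_id`` level with several rows per
    cell (one per glucose condition), the split is performed at the cell
    level so no cell straddles the train/test boundary.
    """
    counts = target.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("both classes need at least 2 members to split")
    if "cell_id" in (matrix.index.names or []):
        cells = matrix.index.get_level_values("cell_id")
        if cells.nunique() < len(matrix):
            per_cell = target.groupby(cells).first()
            tr_cells, te_cells = train_test_split(
                per_cell.index.to_numpy(), test_size=test_fraction,
                random_state=seed, stratify=per_cell.to_numpy())
            tr_mask = np.isin(cells, tr_cells)
            return (matrix.loc[tr_mask], matrix.loc[~tr_mask],
                    target.loc[tr_mask], target.loc[~tr_mask])
    X_tr, X_te, y_tr, y_te = train_test_split(
        matrix, target, test_size=test_fraction, random_state=seed,
        stratify=target)
    return X_tr, X_te, y_tr, y_te


def rebalance_smote(matrix: pd.DataFrame, target: pd.Series,
                    k_neighbors: int = 5, seed: int = 0,
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Equalize class counts by synthetic minority oversampling.

    Synthetic rows interpolate between a minority point and one of its k
    nearest minority neighbors; original rows are returned unchanged.
    Balanced input is returned as-is.
    """
    counts = target.value_counts()
    if len(counts) != 2:
        raise ValueError("SMOTE rebalancing expects exactly two classes")
    minority = counts.idxmin()
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return matrix, target
    Xm = matrix.loc[target == minority]
    n_min = Xm.shape[0]
    if n_min <= k_neighbors:
        k_neighbors = max(1, n_min - 1)
        warnings.warn(
            f"rebalance_smote: minority class too small, reduced "
            f"k_neighbors to {k_neighbors}")
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xm.to_numpy())
    _, idx = nn.kneighbors(Xm.to_numpy())
    base = rng.integers(0, n_min, n_needed)
    pick = rng.integers(1, k_neighbors + 1, n_needed)  # skip self at col 0
    u = rng.uniform(0.0, 1.0, n_needed)
    Xb = Xm.to_numpy()[base]
    Xn = Xm.to_numpy()[idx[base, pick]]
    synth = Xb + u[:, None] * (Xn - Xb)
    synth_idx = (pd.MultiIndex.from_tuples(
        [("synthetic",) * (matrix.index.nlevels - 1) + (f"S{i:04d}",)
         for i in range(n_needed)], names=matrix.index.names)
        if matrix.index.nlevels > 1
        else pd.Index([f"S{i:04d}" for i in range(n_needed)]))
    synth_df = pd.DataFrame(synth, columns=matrix.columns, index=synth_idx)
    out_X = pd.concat([matrix, synth_df])
    out_y = pd.concat([target, pd.Series([minority] * n_needed,
                                         index=synth_idx, name=target.name)])
    return out_X, out_y


@dataclass
class PreprocessedData:
    """Everything downstream training and the stability battery consume."""

    X_train: pd.DataFrame
    y_train: pd.Series
    X_test: pd.DataFrame
    y_test: pd.Series
    X_excluded: pd.DataFrame
    y_excluded: pd.Series
    state: PreprocessState
    outlier_flags: np.ndarray


def run_preprocessing(matrix: pd.DataFrame, target: pd.Series,
                      manifest: CleaningManifest | None = None,
                      test_fraction: float = 0.25, seed: int = 0,
                      lof_neighbors: int = 20,
                      smote_k: int = 5,
                      pool_before_split: bool = False) -> PreprocessedData:
    """Run the full frozen chain and return all partitions plus the state.

    Default mode fits outlier handling and scaling on the training
    partition only and applies SMOTE to the training partition only;
    ``pool_before_split`` fits on (and rebalances) the whole cleaned
    dataset before splitting.
    """
    if manifest is None:
        manifest = CleaningManifest()
    X, y, X_exc, y_exc = clean(matrix, target, manifest)
    X = impute_missing(encode_categoricals(X))
    X_exc = impute_missing(encode_categoricals(X_exc))

    if pool_before_split:
        X, flags, _ = replace_outliers(X, n_neighbors=lof_neighbors)
        X_scaled, state = scale_minmax(X)
        X_bal, y_bal = rebalance_smote(X_scaled, y, k_neighbors=smote_k,
                                       seed=seed)
        X_tr, X_te, y_tr, y_te = split_stratified(
            X_bal, y_bal, test_fraction=test_fraction, seed=seed)
    else:
        X_tr, X_te, y_tr, y_te = split_stratified(
            X, y, test_fraction=test_fraction, seed=seed)
        X_tr, flags, means = replace_outliers(X_tr, n_neighbors=lof_neighbors)
        X_tr_scaled, state = scale_minmax(X_tr)
        X_te = state.transform(X_te)
        X_tr, y_tr = rebalance_smote(X_tr_scaled, y_tr, k_neighbors=smote_k,
                                     seed=seed)
    X_exc_t = state.transform(X_exc) if len(X_exc) else X_exc
    return PreprocessedData(
        X_train=X_tr, y_train=y_tr, X_test=X_te, y_test=y_te,
        X_excluded=X_exc_t, y_excluded=y_exc,
        state=state, outlier_flags=flags)
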