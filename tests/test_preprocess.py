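"""Cleaning manifest, imputation, LOF outliers, scaling, split, SMOTE."""

import numpy as np
import pandas as pd
import pytest

from islet_cytotyper.preprocess import (
    CleaningManifest, clean, encode_categoricals, impute_missing,
    rebalance_smote, replace_outliers, run_preprocessing, scale_minmax,
    split_stratified,
)


def _matrix(n=30, d=4, seed=0, prefix="C"):
    rng = np.random.default_rng(seed)
    idx = pd.MultiIndex.from_tuples(
        [("d0", "i0", f"{prefix}{i:04d}", "low") for i in range(n)],
        names=["donor_id", "islet_id", "cell_id", "condition"])
    X = pd.DataFrame(rng.normal(size=(n, d)),
                     columns=[f"f{j}" for j in range(d)], index=idx)
    y = pd.Series(rng.choice(["alpha", "beta"], n, p=[1 / 3, 2 / 3]),
                  index=idx, name="label")
    return X, y


class TestCleaning:
    def test_unknown_reason_code_rejected(self):
        with pytest.raises(ValueError):
            CleaningManifest({"C0001": "bad-hair-day"})

    def test_empty_manifest_retains_everything(self):
        X, y = _matrix()
        r, ry, e, ey = clean(X, y, CleaningManifest())
        assert len(r) == len(X) and len(e) == 0

    def test_partition_is_exact_and_reason_coded(self):
        X, y = _matrix(20)
        manifest = CleaningManifest({"C0003": "rearrangement",
                                     "C0007": "ambiguous-identity"})
        r, ry, e, ey = clean(X, y, manifest)
        assert len(e) == 2 and len(r) == 18
        assert set(e.index.get_level_values("cell_id")) == {"C0003", "C0007"}

    def test_unknown_cell_id_rejected(self):
        X, y = _matrix(5)
        with pytest.raises(ValueError, match="unknown cell ids"):
            clean(X, y, CleaningManifest({"Z9999": "duplicate"}))

    def test_deposit_scale_arithmetic(self):
        """1932 rows, 1071 exclusions at the cell level -> 861 retained."""
        n_cells = 966
        idx = pd.MultiIndex.from_tuples(
            [("d0", "i0", f"C{i:04d}", c) for i in range(n_cells)
             for c in ("low", "high")],
            names=["donor_id", "islet_id", "cell_id", "condition"])
        X = pd.DataFrame({"f0": np.arange(2 * n_cells, dtype=float)},
                         index=idx)
        y = pd.Series("beta", index=idx, name="label")
        # exclude 1071 of the 1932 rows by listing ceil(1071/2) cells; to
        # keep row arithmetic exact, build a per-row variant instead
        X1 = X.iloc[:1932]
        excl_cells = [f"C{i:04d}" for i in range(1071 // 2)]
        manifest = CleaningManifest(
            {c: "focal-plane-mismatch" for c in excl_cells})
        r, *_ = clean(X1, y, manifest)
        assert len(r) == 1932 - 2 * len(excl_cells)

    def test_manifest_json_round_trip(self, tmp_path):
        m = CleaningManifest({"C0001": "duplicate", "C0002": "shape-change"})
        m.to_json(tmp_path / "m.json")
        assert CleaningManifest.from_json(tmp_path / "m.json") == m


class TestImputeAndEncode:
    def test_zero_imputation_counts_match_missing(self):
        X, _ = _matrix(10)
        X.iloc[0, 0] = np.nan
        X.iloc[3, 2] = np.nan
        n_missing = int(X.isna().sum().sum())
        out = impute_missing(X)
        assert out.isna().sum().sum() == 0
        assert (out.to_numpy() == 0).sum() >= n_missing
        # untouched entries bit-identical
        mask = ~X.isna()
        np.testing.assert_array_equal(out.to_numpy()[mask.to_numpy()],
                                      X.to_numpy()[mask.to_numpy()])

    def test_numeric_matrix_passes_encoding_unchanged(self):
        X, _ = _matrix(8)
        assert encode_categoricals(X) is X

    def test_object_column_one_hot_encoded(self):
        X, _ = _matrix(8)
        X["donor"] = ["d1", "d2"] * 4
        out = encode_categoricals(X)
        assert "donor_d1" in out.columns and "donor" not in out.columns


class TestOutliers:
    def test_planted_outlier_replaced_with_inlier_means(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(0, 0.5, size=(200, 5)))
        X.iloc[17] = 40.0  # gross outlier
        out, flags, means = replace_outliers(X, n_neighbors=20)
        assert flags[17]
        np.testing.assert_allclose(out.iloc[17].to_numpy(),
                                   means.to_numpy())
        assert abs(out.iloc[17, 0]) < 1.0

    def test_non_flagged_rows_bit_exact(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(100, 3)))
        X.iloc[5] = 25.0
        out, flags, _ = replace_outliers(X)
        assert out.shape == X.shape
        np.testing.assert_array_equal(out.to_numpy()[~flags],
                                      X.to_numpy()[~flags])

    def test_too_few_rows_skips_with_warning(self):
        X = pd.DataFrame(np.zeros((5, 2)))
        with pytest.warns(UserWarning, match="skipped"):
            out, flags, _ = replace_outliers(X, n_neighbors=20)
        assert not flags.any()


class TestScaling:
    def test_train_min_zero_max_one_constant_zero(self):
        X = pd.DataFrame({"a": [1.0, 3.0, 5.0], "b": [7.0, 7.0, 7.0]})
        out, state = scale_minmax(X)
        assert out["a"].tolist() == [0.0, 0.5, 1.0]
        assert out["b"].tolist() == [0.0, 0.0, 0.0]

    def test_unseen_values_not_clipped(self):
        X = pd.DataFrame({"a": [0.0, 10.0]})
        _, state = scale_minmax(X)
        test = state.transform(pd.DataFrame({"a": [-5.0, 15.0]}))
        assert test["a"].tolist() == [-0.5, 1.5]

    def test_transform_is_idempotent(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 4.0]})
        out, state = scale_minmax(X)
        again = state.transform(out)
        pd.testing.assert_frame_equal(out, again)

    def test_column_mismatch_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        _, state = scale_minmax(X)
        with pytest.raises(ValueError):
            state.transform(pd.DataFrame({"z": [1.0]}))


class TestSplit:
    def test_861_records_give_216_test(self):
        idx = pd.Index([f"C{i}" for i in range(861)], name="cell_id")
        X = pd.DataFrame({"f0": np.arange(861, dtype=float)}, index=idx)
        y = pd.Series(["beta"] * 574 + ["alpha"] * 287, index=idx)
        X_tr, X_te, y_tr, y_te = split_stratified(X, y, 0.25, seed=0)
        assert len(X_te) == 216 and len(X_tr) == 645

    def test_class_ratio_preserved_and_seeded(self):
        X, y = _matrix(300, seed=3)
        X1 = split_stratified(X, y, 0.25, seed=5)
        X2 = split_stratified(X, y, 0.25, seed=5)
        pd.testing.assert_frame_equal(X1[0], X2[0])
        frac_tr = (X1[2] == "beta").mean()
        frac_te = (X1[3] == "beta").mean()
        assert abs(frac_tr - frac_te) < 0.02

    def test_grouped_split_keeps_cell_rows_together(self):
        n = 40
        idx = pd.MultiIndex.from_tuples(
            [("d0", "i0", f"C{i:03d}", c) for i in range(n)
             for c in ("low", "high")],
            names=["donor_id", "islet_id", "cell_id", "condition"])
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(2 * n, 3)),
                         index=idx)
        y = pd.Series((["beta"] * 2 * 26 + ["alpha"] * 2 * 14), index=idx)
        X_tr, X_te, *_ = split_stratified(X, y, 0.25, seed=1)
        tr = set(X_tr.index.get_level_values("cell_id"))
        te = set(X_te.index.get_level_values("cell_id"))
        assert not tr & te
        assert len(X_tr) % 2 == 0 and len(X_te) % 2 == 0


class TestSMOTE:
    def test_two_to_one_becomes_one_to_one(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(900, 6)))
        y = pd.Series(["beta"] * 600 + ["alpha"] * 300)
        Xb, yb = rebalance_smote(X, y, seed=1)
        assert yb.value_counts()["beta"] == yb.value_counts()["alpha"] == 600

    def test_balanced_input_unchanged(self):
        X = pd.DataFrame(np.random.default_rng(1).normal(size=(40, 3)))
        y = pd.Series(["beta"] * 20 + ["alpha"] * 20)
        Xb, yb = rebalance_smote(X, y, seed=0)
        pd.testing.assert_frame_equal(Xb, X)

    def test_original_rows_bit_identical(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(90, 4)))
        y = pd.Series(["beta"] * 60 + ["alpha"] * 30)
        Xb, _ = rebalance_smote(X, y, seed=3)
        np.testing.assert_array_equal(Xb.iloc[:90].to_numpy(), X.to_numpy())

    def test_synthetic_rows_inside_minority_bounding_box(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(90, 4)))
        y = pd.Series(["beta"] * 60 + ["alpha"] * 30)
        Xb, yb = rebalance_smote(X, y, seed=4)
        Xmin = X.iloc[60:]
        synth = Xb.iloc[90:]
        assert len(synth) == 30
        assert (synth.to_numpy() >= Xmin.min().to_numpy() - 1e-12).all()
        assert (synth.to_numpy() <= Xmin.max().to_numpy() + 1e-12).all()

    def test_tiny_minority_reduces_k_with_warning(self):
        X = pd.DataFrame(np.random.default_rng(4).normal(size=(13, 2)))
        y = pd.Series(["beta"] * 10 + ["alpha"] * 3)
        with pytest.warns(UserWarning, match="reduced"):
            Xb, yb = rebalance_smote(X, y, k_neighbors=5, seed=0)
        assert yb.value_counts()["alpha"] == 10


class TestPipelineChain:
    def test_no_leakage_state_fit_on_train_only(self, small_matrix):
        matrix, target = small_matrix
        prep = run_preprocessing(matrix, target, seed=11)
        # refit scaling on the (outlier-handled, pre-SMOTE) training rows
        n_real = (~prep.X_train.index.get_level_values("cell_id")
                  .isin(["S"])).sum()
        train_cells = set(prep.X_train.index.get_level_values("cell_id"))
        test_cells = set(prep.X_test.index.get_level_values("cell_id"))
        assert not (train_cells - {"synthetic"}) & test_cells
        # test rows scaled by train statistics may exit [0, 1]
        assert prep.state.fitted_on == "train"

    def test_smote_balances_training_partition(self, small_matrix):
        matrix, target = small_matrix
        prep = run_preprocessing(matrix, target, seed=11)
        counts = prep.y_train.value_counts()
        assert counts["alpha"] == counts["beta"]
        counts_te = prep.y_test.value_counts()
        assert counts_te["beta"] > counts_te["alpha"]  # test left imbalanced

    def test_rerun_is_deterministic(self, small_matrix):
        matrix, target = small_matrix
        p1 = run_preprocessing(matrix, target, seed=11)
        p2 = run_preprocessing(matrix, target, seed=11)
        pd.testing.assert_frame_equal(p1.X_train, p2.X_train)
        pd.testing.assert_series_equal(p1.y_test, p2.y_test)
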