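"""Feature schema, descriptive statistics, morphology, record assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skimage import draw

from islet_cytotyper import cell_features as cf
from islet_cytotyper.cell_features import (
    CellImageBundle, DonorInfo, FeatureSchema, build_feature_matrix,
    circularity, default_schema, descriptive_stats, extract_cell_features,
    morphology, read_feature_matrix, write_feature_matrix, STAT_NAMES,
)
from islet_cytotyper.synthetic_islet import SynthConfig, generate_feature_matrix


class TestSchema:
    def test_exactly_151_unique_names(self):
        schema = default_schema()
        assert len(schema) == 151
        assert len(set(schema.names)) == 151

    def test_families_cover_the_declared_set(self):
        fams = {d.family for d in default_schema().descriptors}
        assert fams == {"intensity", "phasor", "metabolism", "morphology",
                        "lipofuscin", "donor", "experimental",
                        "intensity-statistics"}

    def test_json_round_trip(self, tmp_path):
        schema = default_schema()
        schema.to_json(tmp_path / "schema.json")
        back = FeatureSchema.from_json(tmp_path / "schema.json")
        assert back == schema and back.names == schema.names

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            FeatureSchema(default_schema().descriptors[:150])


class TestDescriptiveStats:
    def test_constant_vector(self):
        b = descriptive_stats(np.full(40, 3.5))
        assert b.min == b.max == b.mean == b.median == 3.5
        assert b.sd == 0.0 and b.iqr == 0.0 and b.skewness == 0.0
        assert b.mode_bin_center == 3.5

    def test_1_to_100_quantiles_linear_interpolation(self):
        b = descriptive_stats(np.arange(1, 101, dtype=float))
        assert b.q1 == pytest.approx(25.75)
        assert b.q3 == pytest.approx(75.25)
        assert b.whisker_high == 100.0  # fence is beyond the max
        assert b.whisker_low == 1.0

    def test_empty_input_gives_missing_block(self):
        b = descriptive_stats(np.array([]))
        assert all(np.isnan(getattr(b, k)) for k in STAT_NAMES)

    def test_whisker_excludes_far_outlier(self):
        v = np.concatenate([np.arange(1, 101, dtype=float), [1000.0]])
        b = descriptive_stats(v)
        assert b.whisker_high < 1000.0
        assert b.max == 1000.0

    @given(st.integers(0, 2**31 - 1), st.integers(1, 200))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_ordering_invariants_hold(self, seed, n):
        v = np.random.default_rng(seed).normal(size=n) * 10
        b = descriptive_stats(v)
        assert b.min <= b.q1 <= b.median <= b.q3 <= b.max
        assert b.min <= b.whisker_low <= b.whisker_high <= b.max
        assert b.min <= b.mode_bin_center <= b.max
        assert b.iqr == pytest.approx(b.q3 - b.q1)


class TestMorphology:
    def test_analytic_disk_circularity_is_one(self):
        r = 50.0
        assert circularity(np.pi * r**2, 2 * np.pi * r) == pytest.approx(1.0)

    def test_square_mask_circularity(self):
        mask = np.zeros((60, 60), bool)
        mask[10:50, 10:50] = True
        _, _, circ = morphology(mask)
        assert circ == pytest.approx(np.pi / 4, abs=0.03)

    def test_rasterized_disk_close_to_one(self):
        mask = np.zeros((120, 120), bool)
        rr, cc = draw.disk((60, 60), 50)
        mask[rr, cc] = True
        area, perim, circ = morphology(mask)
        assert 0.95 <= circ <= 1.05
        assert area == mask.sum()

    def test_pixel_size_scales_area_quadratically(self):
        mask = np.zeros((40, 40), bool)
        rr, cc = draw.disk((20, 20), 10)
        mask[rr, cc] = True
        a1, p1, c1 = morphology(mask, pixel_size=1.0)
        a2, p2, c2 = morphology(mask, pixel_size=0.5)
        assert a2 == pytest.approx(a1 / 4) and p2 == pytest.approx(p1 / 2)
        assert c2 == pytest.approx(c1)

    def test_multi_component_mask_rejected_with_cell_name(self):
        mask = np.zeros((30, 30), bool)
        mask[2:6, 2:6] = True
        mask[20:24, 20:24] = True
        with pytest.raises(ValueError, match="cellX"):
            morphology(mask, cell_id="cellX")

    def test_one_pixel_wide_mask_rejected(self):
        mask = np.zeros((30, 30), bool)
        mask[5, 2:25] = True
        with pytest.raises(ValueError, match="degenerate"):
            morphology(mask)


def _tiny_bundle_pair(cell="c0", donor="d0", side=41, seed=0):
    rng = np.random.default_rng(seed)
    mask = np.zeros((side, side), bool)
    rr, cc = draw.disk((side // 2, side // 2), side // 3)
    mask[rr, cc] = True
    bundles = {}
    for cond, mm in (("low", 2.2), ("high", 16.7)):
        inten = np.where(mask, rng.poisson(80, (side, side)).astype(float), 0)
        g = np.where(mask, rng.uniform(0.5, 0.8, (side, side)), np.nan)
        s = np.where(mask, rng.uniform(0.3, 0.45, (side, side)), np.nan)
        bundles[cond] = CellImageBundle(
            cell_id=cell, islet_id="i0", donor_id=donor,
            glucose_condition=mm, intensity=inten, g_map=g, s_map=s,
            roi_mask=mask)
    return bundles["low"], bundles["high"]


DONOR = DonorInfo("d0", age=62.0, bmi=25.1, stimulatory_index=2.4)


class TestExtractAndAssemble:
    def test_record_has_exactly_151_values(self):
        low, high = _tiny_bundle_pair()
        rec = extract_cell_features(low, high, DONOR)
        assert len(rec.values) == 151
        assert set(rec.values) == set(default_schema().names)

    def test_extraction_is_deterministic(self):
        low, high = _tiny_bundle_pair()
        r1 = extract_cell_features(low, high, DONOR)
        r2 = extract_cell_features(low, high, DONOR)
        v1 = np.array([r1.values[k] for k in sorted(r1.values)])
        v2 = np.array([r2.values[k] for k in sorted(r2.values)])
        np.testing.assert_array_equal(v1, v2)  # NaN-aware bit equality

    def test_mismatched_cells_rejected(self):
        low, _ = _tiny_bundle_pair("c0")
        _, high = _tiny_bundle_pair("c1")
        with pytest.raises(ValueError):
            extract_cell_features(low, high, DONOR)

    def test_raster_shape_mismatch_rejected(self):
        low, high = _tiny_bundle_pair()
        with pytest.raises(ValueError, match="mismatched shapes"):
            CellImageBundle(cell_id="c0", islet_id="i0", donor_id="d0",
                            glucose_condition=2.2,
                            intensity=low.intensity[:-1],
                            g_map=low.g_map, s_map=low.s_map,
                            roi_mask=low.roi_mask)

    def test_per_condition_layout_doubles_rows(self):
        low, high = _tiny_bundle_pair()
        rec = extract_cell_features(low, high, DONOR, label="beta")
        matrix, target = build_feature_matrix([rec], layout="per_condition")
        assert matrix.shape == (2, 151)
        assert set(matrix["glucose_code"]) == {0.0, 1.0}
        assert list(target) == ["beta", "beta"]

    def test_row_order_invariant_under_shuffling(self):
        recs = []
        for i in range(6):
            low, high = _tiny_bundle_pair(cell=f"c{i}", seed=i)
            recs.append(extract_cell_features(low, high, DONOR,
                                              label="alpha"))
        m1, _ = build_feature_matrix(recs)
        m2, _ = build_feature_matrix(recs[::-1])
        pd.testing.assert_frame_equal(m1, m2)

    def test_empty_record_list_gives_empty_matrix_with_schema(self):
        matrix, target = build_feature_matrix([])
        assert matrix.shape == (0, 151)
        assert list(matrix.columns) == default_schema().names

    def test_csv_round_trip(self, tmp_path, small_matrix):
        matrix, target = small_matrix
        write_feature_matrix(matrix, target, tmp_path / "m.csv")
        m2, t2 = read_feature_matrix(tmp_path / "m.csv")
        assert m2.shape == matrix.shape
        np.testing.assert_allclose(m2.to_numpy(), matrix.to_numpy(),
                                   rtol=1e-12, equal_nan=True)
        assert (tmp_path / "m.schema.json").exists()

    def test_zero_lipofuscin_blocks_missing_then_imputable(self):
        low, high = _tiny_bundle_pair()  # uniform-ish cell: no granules
        rec = extract_cell_features(low, high, DONOR)
        assert rec.values["lipo_granule_count_low"] == 0.0
        assert np.isnan(rec.values["lipo_mean_granule_area_low"])
        assert np.isnan(rec.values["intensity_lipo_low_mean"])
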