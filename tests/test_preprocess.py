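"""Zone mapping and the preprocessing recipe: MICE, robust scaling,
categorical encoding, oversampling, and the 70/30 split."""

import numpy as np
import pandas as pd
import pytest

from cardiorisk.errors import ConfigurationError, InvalidInputError
from cardiorisk.preprocess import (
    FEATURE_COLUMNS,
    FeatureTable,
    add_zone_column,
    encode_categoricals,
    map_num_to_zone,
    mice_impute,
    oversample,
    robust_scale,
    split_70_30,
)
from cardiorisk.simulate import simulate_cohort


def _cohort(n=300, missing=0.0, seed=0):
    return simulate_cohort(n=n, class_proportions=(0.45, 0.28, 0.27),
                           effect_size=1.0, missing_rate=missing,
                           seed=seed).table


class TestZoneMapping:
    @pytest.mark.parametrize("num,scheme,zone", [
        (0, "three", "green"), (1, "three", "yellow"), (2, "three", "red"),
        (3, "three", "red"), (4, "three", "red"),
        (0, "two", "green"), (1, "two", "red"), (2, "two", "red"),
        (4, "two", "red"),
    ])
    def test_mapping(self, num, scheme, zone):
        assert map_num_to_zone(num, scheme) == zone

    def test_out_of_domain_raises(self):
        with pytest.raises(InvalidInputError):
            map_num_to_zone(5, "three")
        with pytest.raises(InvalidInputError):
            map_num_to_zone(0, "four")

    def test_add_zone_column(self):
        table = add_zone_column(_cohort(100), "three")
        expected = [map_num_to_zone(int(v), "three")
                    for v in table.data["num"]]
        assert list(table.data["zone"]) == expected


class TestMice:
    def test_fully_observed_table_is_unchanged(self):
        table = _cohort(120)
        out = mice_impute(table, seed=1)
        pd.testing.assert_frame_equal(out.data, table.data)
        assert out.stage == "imputed"

    def test_linear_column_recovered_within_5_percent(self):
        """chol = 2 * trestbps exactly; 10 % of chol masked."""
        table = _cohort(400, seed=3)
        df = table.data.copy()
        df["chol"] = 2.0 * df["trestbps"]
        rng = np.random.default_rng(9)
        masked = rng.choice(len(df), size=40, replace=False)
        truth = df.loc[masked, "chol"].to_numpy()
        df.loc[masked, "chol"] = np.nan
        out = mice_impute(FeatureTable(df, "raw"), seed=1)
        imputed = out.data.loc[masked, "chol"].to_numpy()
        rel_err = np.abs(imputed - truth) / truth
        assert np.max(rel_err) < 0.05

    def test_observed_values_never_altered(self):
        table = _cohort(200, missing=0.1, seed=4)
        out = mice_impute(table, seed=2)
        observed = ~table.data.isna()
        for col in table.data.columns:
            obs = observed[col]
            np.testing.assert_array_equal(
                out.data.loc[obs, col].to_numpy(),
                table.data.loc[obs, col].to_numpy(),
            )
        assert not out.data.isna().any().any()

    def test_imputed_categoricals_stay_in_domain(self):
        table = _cohort(200, missing=0.15, seed=5)
        out = mice_impute(table, seed=3)
        assert set(out.data["restecg"].unique()) <= {0, 1, 2}
        assert set(out.data["cp"].unique()) <= {1, 2, 3, 4}
        assert set(out.data["slope"].unique()) <= {1, 2, 3}

    def test_entirely_missing_column_raises(self):
        df = _cohort(50).data.copy()
        df["chol"] = np.nan
        with pytest.raises(ConfigurationError):
            mice_impute(FeatureTable(df, "raw"))


class TestRobustScale:
    def test_scaled_columns_have_median_0_iqr_1(self):
        table = mice_impute(_cohort(257), seed=0)
        scaled, _ = robust_scale(table)
        for col in ("age", "trestbps", "chol", "thalach", "oldpeak"):
            vals = scaled.data[col].to_numpy()
            assert np.median(vals) == pytest.approx(0.0, abs=1e-12)
            iqr = np.percentile(vals, 75) - np.percentile(vals, 25)
            assert iqr == pytest.approx(1.0, rel=1e-12)

    def test_integer_column_example(self):
        df = _cohort(100).data.copy()
        df["age"] = np.arange(1.0, 101.0)
        scaled, _ = robust_scale(FeatureTable(df, "raw"),
                                 continuous_cols=["age"])
        vals = scaled.data["age"].to_numpy()
        assert np.median(vals) == 0.0
        assert np.percentile(vals, 75) - np.percentile(vals, 25) == \
            pytest.approx(1.0, rel=1e-12)

    def test_constant_column_centered_with_warning(self):
        df = _cohort(60).data.copy()
        df["chol"] = 200.0
        with pytest.warns(UserWarning, match="zero IQR"):
            scaled, _ = robust_scale(FeatureTable(df, "raw"),
                                     continuous_cols=["chol"])
        np.testing.assert_array_equal(scaled.data["chol"].to_numpy(), 0.0)

    def test_outliers_shrink_relative_to_zscore_scaling(self, rng):
        """Heavy-tailed cholesterol-like sample: the robust standardized
        magnitude of the outliers stays below their z-scores (the IQR of the
        bulk exceeds the outlier-inflated SD here, so robust scaling resists
        the pull of the tail)."""
        base = rng.normal(240, 40, 500)
        outliers = np.array([540.0, 560.0, 564.0])
        chol = np.concatenate([base, outliers])
        robust = (chol - np.median(chol)) / (
            np.percentile(chol, 75) - np.percentile(chol, 25))
        zscore = (chol - chol.mean()) / chol.std()
        assert np.max(np.abs(robust[-3:])) < np.max(np.abs(zscore[-3:]))

    def test_state_reapplies_exactly(self):
        table = mice_impute(_cohort(150), seed=0)
        scaled, state = robust_scale(table)
        again = state.transform(table.data)
        for col in state.columns:
            np.testing.assert_array_equal(scaled.data[col].to_numpy(),
                                          again[col].to_numpy())
        back = state.inverse_transform(scaled.data)
        np.testing.assert_allclose(back["chol"].to_numpy(),
                                   table.data["chol"].to_numpy(), rtol=1e-12)

    def test_missing_values_rejected(self):
        table = _cohort(100, missing=0.1, seed=1)
        with pytest.raises(InvalidInputError):
            robust_scale(table)


class TestEncoding:
    def test_cp_4_maps_to_3(self):
        table = mice_impute(_cohort(150), seed=0)
        encoded, _ = encode_categoricals(robust_scale(table)[0])
        orig = robust_scale(table)[0].data
        np.testing.assert_array_equal(encoded.data["cp"].to_numpy(),
                                      orig["cp"].to_numpy() - 1)
        np.testing.assert_array_equal(encoded.data["sex"].to_numpy(),
                                      orig["sex"].to_numpy())

    def test_round_trip(self):
        table = mice_impute(_cohort(150), seed=0)
        scaled, _ = robust_scale(table)
        encoded, state = encode_categoricals(scaled)
        decoded = state.inverse_transform(encoded.data)
        pd.testing.assert_frame_equal(decoded, scaled.data)

    def test_unseen_category_raises_with_column_name(self):
        df = mice_impute(_cohort(60), seed=0).data.copy()
        df.loc[0, "cp"] = 9
        with pytest.raises(InvalidInputError, match="cp"):
            encode_categoricals(FeatureTable(df, "imputed"))


class TestOversample:
    @staticmethod
    def _labeled(counts, seed=0):
        rows = []
        for cls, cnt in enumerate(counts):
            for i in range(cnt):
                rows.append({"age": 30.0 + i % 40, "num": float(cls)})
        df = pd.DataFrame(rows)
        table = FeatureTable(df, "raw")
        return add_zone_column(table, "three")

    def test_minority_duplicated_to_majority(self):
        table = self._labeled([300, 100])
        out = oversample(table, seed=1)
        counts = out.data["zone"].value_counts()
        assert counts["green"] == 300 and counts["yellow"] == 300

    def test_paper_zone_counts_balance_to_majority(self):
        table = self._labeled([413, 258, 249])
        out = oversample(table, seed=1)
        assert out.data["zone"].value_counts().tolist() == [413, 413, 413]

    def test_balanced_table_unchanged(self):
        table = self._labeled([50, 50])
        out = oversample(table, seed=1)
        pd.testing.assert_frame_equal(out.data, table.data)

    def test_majority_multiset_preserved_and_originals_retained(self):
        table = self._labeled([40, 10])
        out = oversample(table, seed=2)
        # first len(original) rows are the originals, in order
        pd.testing.assert_frame_equal(out.data.iloc[:50], table.data)

    def test_single_class_raises(self):
        table = self._labeled([30])
        with pytest.raises(InvalidInputError):
            oversample(table)


class TestSplit:
    def test_sizes_and_disjointness(self):
        table = add_zone_column(_cohort(100), "three")
        train, test = split_70_30(table, seed=0)
        assert len(train) == 70 and len(test) == 30

    @pytest.mark.parametrize("n", [99, 101, 257])
    def test_train_size_is_round_70_percent(self, n):
        table = add_zone_column(_cohort(n), "three")
        train, test = split_70_30(table, seed=1)
        assert len(train) == int(np.floor(0.7 * n + 0.5))
        assert len(train) + len(test) == n

    def test_same_seed_identical_split(self):
        table = add_zone_column(_cohort(150), "three")
        t1, s1 = split_70_30(table, seed=7, stratified=True)
        t2, s2 = split_70_30(table, seed=7, stratified=True)
        pd.testing.assert_frame_equal(t1.data, t2.data)
        pd.testing.assert_frame_equal(s1.data, s2.data)

    def test_stratified_preserves_class_proportions(self):
        table = add_zone_column(_cohort(400, seed=8), "three")
        train, _ = split_70_30(table, seed=2, stratified=True)
        for zone, n_cls in table.data["zone"].value_counts().items():
            got = (train.data["zone"] == zone).sum()
            assert abs(got - 0.7 * n_cls) <= 1.0

    def test_stratification_with_too_few_records_raises(self):
        # 3 classes but round(0.7 * 3) = 2 training slots
        df = pd.DataFrame({"age": [40.0, 50.0, 60.0], "num": [0.0, 1.0, 2.0]})
        table = add_zone_column(FeatureTable(df, "raw"), "three")
        with pytest.raises(InvalidInputError):
            split_70_30(table, stratified=True)


def test_recipe_is_deterministic_end_to_end():
    from cardiorisk.pipeline import RunConfig, preprocess_table

    table = _cohort(200, missing=0.1, seed=6)
    cfg = RunConfig(scheme="three", seed=13)
    a_train, a_test, _ = preprocess_table(table, cfg)
    b_train, b_test, _ = preprocess_table(table, cfg)
    pd.testing.assert_frame_equal(a_train.data, b_train.data)
    pd.testing.assert_frame_equal(a_test.data, b_test.data)


def test_stage_transitions_are_monotone():
    table = mice_impute(_cohort(80), seed=0)
    with pytest.raises(InvalidInputError):
        mice_impute(table, seed=0)  # imputed -> imputed not allowed
    with pytest.raises(InvalidInputError):
        FeatureTable(pd.DataFrame({"bogus": [1]}), "raw")
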