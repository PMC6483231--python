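import math

import numpy as np
import pytest
from scipy import stats

from adhdtree.cfs_ensemble import (
    EnsembleConfig,
    aggregate_selections,
    cfs_merit,
    cfs_search,
    ensemble_select,
    feature_class_correlation,
    merit_from_correlations,
)
from adhdtree.cohort_io import CohortError
from helpers import exhaustive_merit_oracle, make_table, merit_oracle


def labels_01(y01):
    return ["ADHD" if v else "TD" for v in y01]


class TestFeatureClassCorrelation:
    def test_feature_identical_to_encoding(self):
        y = [0, 0, 1, 1, 0, 1]
        assert feature_class_correlation(np.array(y, float), labels_01(y)) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        r = feature_class_correlation([1.0, 2.0, 3.0, 4.0], ["TD", "TD", "ADHD", "ADHD"])
        assert r == pytest.approx(2.0 / math.sqrt(5.0), abs=1e-12)

    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=1000)
        y = labels_01(rng.integers(0, 2, size=1000))
        assert feature_class_correlation(x, y) < 0.1

    def test_zero_variance_feature_is_zero(self):
        assert feature_class_correlation([3.0] * 10, labels_01([0] * 5 + [1] * 5)) == 0.0

    def test_matches_scipy_pearson(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        y01 = rng.integers(0, 2, size=50)
        expected = abs(stats.pearsonr(x, y01).statistic)
        assert feature_class_correlation(x, labels_01(y01)) == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(CohortError):
            feature_class_correlation([1.0, 2.0, 3.0], ["TD", "TD", "TD"])


class TestMerit:
    def test_closed_form(self):
        # k=2, mean r_cf=(0.6+0.5)/2, r_ff=0.2
        assert merit_from_correlations(2, 0.55, 0.2) == pytest.approx(1.1 / math.sqrt(2.4))

    def test_singleton_merit_is_class_correlation(self):
        rng = np.random.default_rng(2)
        y01 = rng.integers(0, 2, size=40)
        x = y01 + rng.normal(0, 0.8, size=40)
        table = make_table(x[:, None], labels_01(y01))
        r = feature_class_correlation(x, labels_01(y01))
        assert cfs_merit(["f0"], table) == pytest.approx(r, abs=1e-12)

    def test_duplicate_adds_nothing(self):
        rng = np.random.default_rng(3)
        y01 = rng.integers(0, 2, size=40)
        x = y01 + rng.normal(0, 0.8, size=40)
        table = make_table(np.column_stack([x, x]), labels_01(y01))
        assert cfs_merit(["f0", "f1"], table) == pytest.approx(
            cfs_merit(["f0"], table), abs=1e-12
        )

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(5)
        y01 = rng.integers(0, 2, size=60)
        X = rng.normal(size=(60, 4)) + y01[:, None] * rng.uniform(0, 1, size=4)
        table = make_table(X, labels_01(y01))
        subset = ["f0", "f2", "f3"]
        assert cfs_merit(subset, table) == pytest.approx(merit_oracle(table, subset), abs=1e-10)

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(6)
        y01 = rng.integers(0, 2, size=50)
        X = rng.normal(size=(50, 3)) + y01[:, None]
        table = make_table(X, labels_01(y01))
        X2 = X * np.array([2.0, -0.5, 100.0]) + np.array([1.0, -7.0, 0.003])
        table2 = make_table(X2, labels_01(y01))
        subset = ["f0", "f1", "f2"]
        assert cfs_merit(subset, table2) == pytest.approx(cfs_merit(subset, table), abs=1e-9)


class TestSearch:
    def test_finds_single_informative_feature(self):
        rng = np.random.default_rng(7)
        y01 = rng.integers(0, 2, size=200)
        X = rng.normal(size=(200, 10))
        X[:, 4] = y01  # perfectly correlated column
        table = make_table(X, labels_01(y01))
        selected = cfs_search(table)
        assert selected == {"f4"}
        assert cfs_merit(selected, table) == pytest.approx(exhaustive_merit_oracle(table), abs=1e-9)

    def test_identical_informative_features_select_one(self):
        rng = np.random.default_rng(8)
        y01 = rng.integers(0, 2, size=100)
        x = y01 + rng.normal(0, 0.5, size=100)
        X = np.column_stack([x, x, rng.normal(size=100)])
        table = make_table(X, labels_01(y01))
        selected = cfs_search(table)
        assert len(selected & {"f0", "f1"}) == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_attains_exhaustive_maximum(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, p = 60, 8
        y01 = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, p)) + y01[:, None] * rng.uniform(0, 0.8, size=p)
        table = make_table(X, labels_01(y01))
        best = cfs_search(table)
        assert cfs_merit(best, table) == pytest.approx(exhaustive_merit_oracle(table), abs=1e-9)


class TestEnsemble:
    def test_inclusive_aggregation_threshold(self):
        universe = ["a", "b", "c"]
        sets = [{"a"}] * 5 + [{"b"}] * 4 + [set()] * 11
        freq, selected = aggregate_selections(sets, 20, 0.25, universe)
        assert freq == {"a": 0.25, "b": 0.2, "c": 0.0}
        assert selected == ("a",)  # 5/20 kept, 4/20 dropped

    def test_frequencies_on_grid_and_rule(self, planted_train):
        from adhdtree.feature_extraction import build_feature_table

        table = build_feature_table(planted_train, roi_subset=[40, 88, 1], phenotypes=("gender",))
        config = EnsembleConfig(n_resamples=10, seed=21)
        result = ensemble_select(table, config)
        grid = {i / 10 for i in range(11)}
        assert set(result.frequency.values()) <= grid
        expected = tuple(
            f for f in table.feature_names if result.frequency[f] >= config.frequency_threshold
        )
        assert result.selected == expected

    def test_deterministic_given_seed(self, planted_train):
        from adhdtree.feature_extraction import build_feature_table

        table = build_feature_table(planted_train, roi_subset=[40, 88, 1], phenotypes=("gender",))
        r1 = ensemble_select(table, EnsembleConfig(n_resamples=8, seed=5))
        r2 = ensemble_select(table, EnsembleConfig(n_resamples=8, seed=5))
        assert r1.selected == r2.selected
        assert r1.per_resample_sets == r2.per_resample_sets

    def test_strong_effect_selected_in_most_resamples(self, planted_train):
        from adhdtree.feature_extraction import build_feature_table

        table = build_feature_table(planted_train, roi_subset=[40, 1, 2], phenotypes=("gender",))
        result = ensemble_select(table, EnsembleConfig(seed=13))
        assert result.frequency["roi_40_var"] >= 0.9

    def test_single_class_table_rejected(self):
        table = make_table(np.zeros((10, 2)), ["TD"] * 10)
        with pytest.raises(CohortError):
            ensemble_select(table, EnsembleConfig(seed=1))
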