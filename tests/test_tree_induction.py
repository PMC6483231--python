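import json

import numpy as np
import pytest

from adhdtree.cohort_io import CohortError
from adhdtree.feature_extraction import build_feature_table
from adhdtree.tree_induction import (
    ClassCounts,
    best_numeric_split,
    entropy,
    grow,
    information_gain,
    leaf_sizes,
    model_from_json,
    predict,
    predict_table,
    render,
    split_features,
    training_accuracy,
    validate_model,
)
from helpers import entropy_oracle, gain_oracle, make_table, split_oracle


class TestEntropy:
    def test_pure_node_is_zero(self):
        assert entropy(ClassCounts(10, 0)) == 0.0

    def test_balanced_node_is_one(self):
        assert entropy(ClassCounts(5, 5)) == pytest.approx(1.0)

    def test_training_set_class_mix(self):
        # 93 TD / 117 ADHD, direct evaluation of the formula
        assert entropy(ClassCounts(93, 117)) == pytest.approx(0.9905577004075261, abs=1e-12)

    def test_empty_node_rejected(self):
        with pytest.raises(CohortError):
            entropy(ClassCounts(0, 0))

    def test_random_counts_match_direct_formula(self):
        rng = np.random.default_rng(31)
        for _ in range(300):
            a, b = int(rng.integers(0, 50)), int(rng.integers(0, 50))
            if a + b == 0:
                continue
            assert entropy(ClassCounts(a, b)) == pytest.approx(
                entropy_oracle((a, b)), abs=1e-12
            )
            assert 0.0 <= entropy(ClassCounts(a, b)) <= 1.0


class TestInformationGain:
    def test_proportional_children_give_zero(self):
        parent = ClassCounts(6, 4)
        kids = [ClassCounts(3, 2), ClassCounts(3, 2)]
        assert information_gain(parent, kids) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_split_of_balanced_node(self):
        assert information_gain(
            ClassCounts(5, 5), [ClassCounts(5, 0), ClassCounts(0, 5)]
        ) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        got = information_gain(ClassCounts(6, 4), [ClassCounts(5, 1), ClassCounts(1, 3)])
        assert got == pytest.approx(0.256425891682003, abs=1e-12)

    def test_count_mismatch_rejected(self):
        with pytest.raises(CohortError):
            information_gain(ClassCounts(5, 5), [ClassCounts(5, 0), ClassCounts(0, 4)])

    def test_random_splits_match_direct_formula(self):
        rng = np.random.default_rng(32)
        for _ in range(300):
            a, b = int(rng.integers(1, 40)), int(rng.integers(1, 40))
            al, bl = int(rng.integers(0, a + 1)), int(rng.integers(0, b + 1))
            kids = [ClassCounts(al, bl), ClassCounts(a - al, b - bl)]
            got = information_gain(ClassCounts(a, b), kids)
            want = gain_oracle((a, b), [(al, bl), (a - al, b - bl)])
            assert got == pytest.approx(want, abs=1e-12)
            assert got >= -1e-12


class TestBestNumericSplit:
    def test_perfectly_separable(self):
        values = np.arange(1.0, 11.0)
        labels = ["TD"] * 5 + ["ADHD"] * 5
        theta, gain = best_numeric_split(values, labels, m=2)
        assert theta == pytest.approx(5.5)
        assert gain == pytest.approx(1.0)

    def test_constant_feature_has_no_split(self):
        assert best_numeric_split(np.ones(10), ["TD"] * 5 + ["ADHD"] * 5, m=2) is None

    def test_too_small_node_has_no_split(self):
        assert best_numeric_split(np.arange(9.0), ["TD"] * 4 + ["ADHD"] * 5, m=5) is None

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_midpoint_scan(self, seed):
        rng = np.random.default_rng(200 + seed)
        values = rng.choice(np.linspace(0, 1, 12), size=30)  # force tied values
        y01 = rng.integers(0, 2, size=30)
        labels = ["ADHD" if v else "TD" for v in y01]
        got = best_numeric_split(values, labels, m=5)
        want = split_oracle(values, y01, m=5)
        if want is None:
            assert got is None
        else:
            assert got[0] == pytest.approx(want[0])
            assert got[1] == pytest.approx(want[1], abs=1e-12)


def separable_table(n=30, m_margin=None):
    rng = np.random.default_rng(77)
    x = np.concatenate([rng.uniform(0, 1, n // 2), rng.uniform(2, 3, n - n // 2)])
    labels = ["TD"] * (n // 2) + ["ADHD"] * (n - n // 2)
    return make_table(x[:, None], labels, names=["signal"])


class TestGrow:
    def test_gender_alone_separates(self):
        gender = ["F"] * 10 + ["M"] * 10
        labels = ["TD"] * 10 + ["ADHD"] * 10
        table = make_table(np.zeros((20, 1)), labels, names=["junk"], gender=gender)
        model = grow(table, m=5)
        assert model.root.feature == "gender"
        assert all(c.is_leaf for c in model.root.children)
        assert predict(model, {"gender": "F"})[0] == "TD"
        assert predict(model, {"gender": "M"})[0] == "ADHD"

    def test_pure_table_gives_single_leaf(self):
        table = make_table(np.random.default_rng(1).normal(size=(8, 2)), ["TD"] * 8)
        model = grow(table, m=2)
        assert model.root.is_leaf and model.root.prediction == "TD"

    def test_training_fit_on_separable_table(self):
        table = separable_table(30)
        model = grow(table, m=5)
        assert training_accuracy(model, table) == 1.0

    def test_recovers_planted_gender_conditional_structure(self, planted_train):
        table = build_feature_table(planted_train, roi_subset=[40, 88], phenotypes=("gender",))
        model = grow(table, m=5)
        assert split_features(model) <= {"gender", "roi_40_var", "roi_88_var"}
        assert "roi_40_var" in split_features(model)


class TestPredict:
    def test_single_leaf_has_empty_chain(self):
        table = make_table(np.zeros((6, 1)), ["TD"] * 6)
        model = grow(table, m=2)
        label, chain = predict(model, {"f0": 123.0})
        assert label == "TD" and chain == []

    def test_value_at_threshold_goes_left(self):
        table = separable_table(20)
        model = grow(table, m=5)
        theta = model.root.threshold
        label, chain = predict(model, {"signal": theta})
        assert chain[0] == ("signal", "<=", theta)
        assert label == "TD"

    def test_missing_feature_rejected(self):
        table = separable_table(20)
        model = grow(table, m=5)
        with pytest.raises(CohortError, match="signal"):
            predict(model, {"other": 1.0})

    def test_matches_independent_node_descent(self, planted_train):
        from adhdtree.tree_induction import model_to_dict

        table = build_feature_table(planted_train, roi_subset=[40, 88], phenotypes=("gender",))
        model = grow(table, m=5)
        d = model_to_dict(model)

        def oracle(row):
            node = d["root"]
            while "children" in node:
                if node["kind"] == "numeric":
                    node = node["children"][0 if row[node["feature"]] <= node["threshold"] else 1]
                else:
                    node = node["children"][node["categories"].index(row[node["feature"]])]
            return node["prediction"]

        rows = table.values.to_dict("records")
        assert predict_table(model, table) == [oracle(r) for r in rows]


class TestRender:
    def test_single_leaf_one_line(self):
        table = make_table(np.zeros((6, 1)), ["TD"] * 6)
        model = grow(table, m=2)
        text = render(model, fmt="text")
        assert text == "=> TD  [TD=6, ADHD=0]"

    def test_json_round_trip_is_byte_identical(self, planted_train, atlas):
        table = build_feature_table(planted_train, roi_subset=[40, 88], phenotypes=("gender",))
        model = grow(table, m=5)
        blob = render(model, fmt="json")
        again = render(model_from_json(blob), fmt="json")
        assert again == blob

    def test_text_uses_atlas_names(self, planted_train, atlas):
        table = build_feature_table(planted_train, roi_subset=[40], phenotypes=())
        model = grow(table, m=5)
        text = render(model, atlas=atlas, fmt="text")
        assert "variance of Parahippocampal gyrus (R)" in text

    def test_dot_output(self, planted_train):
        table = build_feature_table(planted_train, roi_subset=[40], phenotypes=())
        model = grow(table, m=5)
        dot = render(model, fmt="dot")
        assert dot.startswith("digraph") and "->" in dot

    def test_unknown_format_rejected(self):
        table = make_table(np.zeros((6, 1)), ["TD"] * 6)
        with pytest.raises(CohortError):
            render(grow(table, m=2), fmt="pdf")


class TestStructuralInvariants:
    @pytest.mark.parametrize("m", [1, 2, 5, 10])
    def test_trained_models_satisfy_invariants(self, planted_train, m):
        table = build_feature_table(planted_train, roi_subset=[40, 88, 1], phenotypes=("gender",))
        model = grow(table, m)
        validate_model(model)
        assert min(leaf_sizes(model)) >= min(m, table.n)

    def test_leaf_count_non_increasing_in_m(self, planted_train):
        table = build_feature_table(planted_train, roi_subset=[40, 88, 1], phenotypes=("gender",))
        counts = [len(leaf_sizes(grow(table, m))) for m in range(1, 16)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_growth_is_deterministic(self, planted_train):
        table = build_feature_table(planted_train, roi_subset=[40, 88], phenotypes=("gender",))
        t1 = render(grow(table, 5), fmt="json")
        t2 = render(grow(table, 5), fmt="json")
        assert t1 == t2
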