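"""CART fitting, prediction, biomarker extraction, determinism."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

from iema.tree import (
    TreeParams,
    accuracy,
    extract_biomarkers,
    fit_cart,
    predict_frame,
    predict_tree,
)


def frame(X, genes=None, samples=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{j}" for j in range(X.shape[1])]
    samples = samples or [f"s{i}" for i in range(X.shape[0])]
    return pd.DataFrame(X, index=samples, columns=genes)


class TestFit:
    def test_single_gene_separation(self):
        expr = frame([[10.0], [11.0], [100.0], [105.0]], genes=["CD48"])
        labels = ["a", "a", "b", "b"]
        model = fit_cart(expr, labels, TreeParams(min_leaf=1, max_depth=3))
        assert not model.root.is_leaf
        assert model.root.gene == "CD48"
        assert accuracy(model, expr, labels) == 1.0

    def test_xor_needs_depth_two(self):
        # no single split reduces Gini on XOR, so zero-decrease splits must
        # be admitted (negative complexity) for the depth-2 tree to form
        expr = frame([[0, 0], [0, 1], [1, 0], [1, 1]])
        labels = ["a", "b", "b", "a"]
        deep = fit_cart(expr, labels, TreeParams(min_leaf=1, max_depth=2, complexity=-1.0))
        assert accuracy(deep, expr, labels) == 1.0
        shallow = fit_cart(expr, labels, TreeParams(min_leaf=1, max_depth=1, complexity=-1.0))
        assert accuracy(shallow, expr, labels) <= 0.75

    def test_single_class_gives_single_leaf(self):
        expr = frame(np.arange(8).reshape(4, 2))
        model = fit_cart(expr, ["a"] * 4, TreeParams(min_leaf=1))
        assert model.root.is_leaf
        assert extract_biomarkers(model) == []

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            fit_cart(frame(np.empty((0, 2))), [])

    def test_missing_values_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_cart(frame(X), ["a", "a", "b", "b"], TreeParams(min_leaf=1))

    def test_gini_decrease_non_negative_at_every_split(self):
        rng = np.random.default_rng(0)
        expr = frame(rng.normal(0, 1, (120, 10)))
        labels = rng.choice(["a", "b", "c"], 120)
        model = fit_cart(expr, labels, TreeParams(min_leaf=5, max_depth=4))

        def gini(counts):
            n = sum(counts.values())
            return 1 - sum((c / n) ** 2 for c in counts.values())

        def walk(node):
            if node.is_leaf:
                return
            nl = sum(node.left.class_counts.values())
            nr = sum(node.right.class_counts.values())
            parent = gini(node.class_counts)
            child = (nl * gini(node.left.class_counts) + nr * gini(node.right.class_counts)) / (nl + nr)
            assert child <= parent + 1e-12
            walk(node.left)
            walk(node.right)

        walk(model.root)

    def test_accuracy_non_decreasing_in_depth(self):
        rng = np.random.default_rng(1)
        expr = frame(rng.normal(0, 1, (150, 8)))
        labels = rng.choice(["a", "b"], 150)
        prev = 0.0
        for depth in (1, 2, 3, 5):
            model = fit_cart(expr, labels, TreeParams(min_leaf=5, max_depth=depth))
            acc = accuracy(model, expr, labels)
            assert acc >= prev - 1e-12
            prev = acc

    def test_permuting_sample_order_yields_identical_tree(self):
        rng = np.random.default_rng(2)
        expr = frame(rng.normal(0, 1, (80, 6)))
        labels = pd.Series(rng.choice(["a", "b", "c"], 80), index=expr.index)
        model1 = fit_cart(expr, labels, TreeParams(min_leaf=4, max_depth=4))
        perm = rng.permutation(80)
        model2 = fit_cart(expr.iloc[perm], labels.iloc[perm], TreeParams(min_leaf=4, max_depth=4))
        assert model1.to_dict() == model2.to_dict()

    def test_root_split_matches_sklearn_on_continuous_data(self):
        # independent check of the Gini split search against sklearn's CART
        rng = np.random.default_rng(3)
        expr = frame(np.round(rng.normal(0, 1, (100, 5)), 3))
        labels = (expr["g2"] + 0.3 * rng.normal(size=100) > 0).map({True: "hi", False: "lo"})
        mine = fit_cart(expr, labels, TreeParams(min_leaf=5, max_depth=1))
        sk = DecisionTreeClassifier(max_depth=1, min_samples_leaf=5, random_state=0)
        sk.fit(expr.to_numpy(), labels.to_numpy())
        assert mine.root.gene == expr.columns[sk.tree_.feature[0]]
        assert mine.root.threshold == pytest.approx(sk.tree_.threshold[0], abs=1e-6)


class TestPredict:
    def test_threshold_routes_right_at_boundary(self):
        expr = frame([[1.0], [1.0], [3.0], [3.0]], genes=["g"])
        model = fit_cart(expr, ["a", "a", "b", "b"], TreeParams(min_leaf=1, max_depth=1))
        assert model.root.threshold == pytest.approx(2.0)
        # value exactly at the threshold goes right (at-or-above)
        assert predict_tree(model, {"g": 2.0}) == "b"
        assert predict_tree(model, {"g": 1.999}) == "a"

    def test_training_sample_from_pure_leaf_predicted_correctly(self):
        expr = frame([[10.0], [12.0], [90.0], [95.0]], genes=["g"])
        labels = ["a", "a", "b", "b"]
        model = fit_cart(expr, labels, TreeParams(min_leaf=1))
        assert list(predict_frame(model, expr)) == labels

    def test_missing_split_gene_errors(self):
        expr = frame([[1.0], [1.0], [3.0], [3.0]], genes=["g"])
        model = fit_cart(expr, ["a", "a", "b", "b"], TreeParams(min_leaf=1, max_depth=1))
        with pytest.raises(ValueError, match="missing split gene"):
            predict_tree(model, {"other": 5.0})


class TestBiomarkers:
    def test_stump_biomarker(self):
        expr = frame([[10.0], [12.0], [90.0], [95.0]], genes=["CD48"])
        model = fit_cart(expr, ["a", "a", "b", "b"], TreeParams(min_leaf=1, max_depth=1))
        assert extract_biomarkers(model) == ["CD48"]

    def test_count_bounded_by_internal_nodes(self):
        rng = np.random.default_rng(4)
        expr = frame(rng.normal(0, 1, (200, 10)))
        labels = rng.choice(["a", "b", "c", "d"], 200)
        model = fit_cart(expr, labels, TreeParams(min_leaf=5, max_depth=3))
        assert len(extract_biomarkers(model)) <= 7  # depth-3 binary tree bound


def test_marker_fixture_uses_all_planted_markers():
    # one diagnostic gene per class: every marker must appear as a split gene
    rng = np.random.default_rng(5)
    n_per = 30
    classes = ["c1", "c2", "c3"]
    markers = ["M1", "M2", "M3"]
    X = rng.normal(5, 0.3, (n_per * 3, 4))
    for k in range(3):
        X[k * n_per : (k + 1) * n_per, k] += 10
    expr = frame(X, genes=markers + ["noise"])
    labels = np.repeat(classes, n_per)
    model = fit_cart(expr, labels, TreeParams(min_leaf=5, max_depth=3))
    assert accuracy(model, expr, labels) == 1.0
    assert set(extract_biomarkers(model)) >= {"M1", "M2"}  # 2 splits separate 3 classes
    assert set(extract_biomarkers(model)) <= set(markers)


def test_synthetic_cohort_biomarkers_are_planted_genes(small_cohort):
    # split genes on the planted cohort must be cluster-informative genes
    truth = small_cohort.true_clusters
    tumor = small_cohort.counts.tumor()
    clustered = [s for s, g in truth.items() if g != "background"]
    expr = np.log2(tumor[clustered] + 1).T
    labels = {s: truth[s] for s in clustered}
    model = fit_cart(expr, labels, TreeParams(min_leaf=5, max_depth=6))
    markers = extract_biomarkers(model)
    assert markers
    # every split gene must carry real between-group signal: its group means
    # must separate by far more than noise allows at layer_effect = 4
    for g in markers:
        by_group = {}
        for s in clustered:
            by_group.setdefault(truth[s], []).append(tumor.at[g, s])
        means = [np.mean(v) for v in by_group.values()]
        assert max(means) > 2.5 * (min(means) + 1), g
    # held-out check: refit on half, predict the other half
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(clustered))
    half = len(clustered) // 2
    train = [clustered[i] for i in perm[:half]]
    test = [clustered[i] for i in perm[half:]]
    m2 = fit_cart(expr.loc[train], {s: truth[s] for s in train}, TreeParams(min_leaf=5, max_depth=6))
    assert accuracy(m2, expr.loc[test], {s: truth[s] for s in test}) >= 0.9
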