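import itertools

import numpy as np
import pandas as pd
import pytest

from pearlsex import SimConfig, simulate_ct
from pearlsex.features import ratio_features
from pearlsex.mrt import (
    MRTParams,
    cross_validate,
    encode_response,
    fit_mrt,
    grow,
    predict,
    prune_sequence,
    select_tree,
    variance_partition,
)
from pearlsex.qpcr import relative_expression


def _ss(y):
    y = np.asarray(y, dtype=float)
    return ((y - y.mean(axis=0)) ** 2).sum()


from tests_oracles import exhaustive_best_split as _exhaustive_best_split  # noqa: E402


class TestEncodeResponse:
    def test_one_hot(self):
        resp = encode_response(["MP", "FP", "MP"])
        np.testing.assert_array_equal(resp.to_numpy(), [[1, 0], [0, 1], [1, 0]])

    def test_column_sums_are_class_counts(self):
        resp = encode_response(["a", "b", "a", "c", "a"])
        assert resp.sum(axis=0).tolist() == [3, 1, 1]

    def test_single_class_refused(self):
        with pytest.raises(ValueError):
            encode_response(["MP", "MP"])


class TestGrow:
    def test_perfectly_separating_feature_single_split(self):
        X = pd.DataFrame({"f": [0.1, 0.2, 5.0, 6.0, 0.15, 5.5]})
        y = encode_response(["a", "a", "b", "b", "a", "b"])
        tree = grow(X, y, MRTParams(minsplit=2, minbucket=1))
        assert tree.n_leaves == 2
        assert tree.relative_error == pytest.approx(0.0)
        assert tree.root.feature == "f"

    def test_greedy_split_matches_exhaustive_oracle(self, rng):
        for trial in range(20):
            n, p = rng.integers(8, 21), rng.integers(1, 5)
            X = pd.DataFrame(
                rng.lognormal(size=(n, p)), columns=[f"f{j}" for j in range(p)]
            )
            labels = rng.choice(["a", "b", "c"], size=n)
            if len(set(labels)) < 2:
                continue
            y = encode_response(labels)
            tree = grow(X, y, MRTParams(minsplit=2, minbucket=1, cp=0.0))
            expected = _exhaustive_best_split(X.to_numpy(), y.to_numpy())
            if expected is None:
                assert tree.root.is_leaf
                continue
            j, thr, dss = expected
            assert tree.root.feature_idx == j
            assert tree.root.threshold == pytest.approx(thr)
            assert tree.root.delta_ss == pytest.approx(dss)

    def test_conservation_of_sum_of_squares(self, rng):
        """SS(root) = sum of split dSS + sum of leaf SS (to 1e-9 rel)."""
        for trial in range(10):
            X = pd.DataFrame(rng.lognormal(size=(30, 4)))
            y = encode_response(rng.choice(list("abcd"), size=30))
            tree = grow(X, y, MRTParams(minsplit=4, minbucket=2, cp=0.0))
            total = sum(nd.delta_ss for nd in tree.root.internal()) + sum(
                l.ss for l in tree.root.leaves()
            )
            assert total == pytest.approx(tree.ss_root, rel=1e-9)

    def test_minbucket_respected(self, rng):
        X = pd.DataFrame(rng.lognormal(size=(20, 3)))
        y = encode_response(rng.choice(["a", "b"], size=20))
        tree = grow(X, y, MRTParams(minsplit=6, minbucket=3, cp=0.0))
        for leaf in tree.root.leaves():
            assert leaf.n >= 3

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError):
            grow(pd.DataFrame(index=[0, 1]), encode_response(["a", "b"]))

    def test_univariate_matches_sklearn_oracle(self, rng):
        """With a 1-column response the root split equals a standard
        regression-tree stump's (scikit-learn as independent oracle)."""
        from sklearn.tree import DecisionTreeRegressor

        for trial in range(10):
            X = pd.DataFrame(rng.lognormal(size=(25, 3)))
            yv = rng.normal(size=25)
            y = pd.DataFrame({"y": yv})
            tree = grow(X, y, MRTParams(minsplit=2, minbucket=1, cp=0.0))
            stump = DecisionTreeRegressor(max_depth=1).fit(X, yv)
            if tree.root.is_leaf:
                continue
            assert tree.root.feature_idx == stump.tree_.feature[0]
            # sklearn computes thresholds in float32 input space
            assert tree.root.threshold == pytest.approx(stump.tree_.threshold[0], rel=1e-6)


class TestPruneAndCV:
    def _dataset(self, rng, n=40):
        X = pd.DataFrame(rng.lognormal(size=(n, 4)), columns=list("wxyz"))
        y = encode_response(rng.choice(["a", "b", "c"], size=n))
        return X, y

    def test_root_only_tree_has_single_cp_row(self):
        X = pd.DataFrame({"f": [1.0, 1.0, 1.0, 1.0]})
        y = encode_response(["a", "b", "a", "b"])
        tree = grow(X, y, MRTParams(minsplit=2, minbucket=1))
        seq = prune_sequence(tree)
        assert len(seq) == 1 and seq[0][1].relative_error == pytest.approx(1.0)

    def test_cp_sequence_nested_and_monotone(self, rng):
        for _ in range(10):
            X, y = self._dataset(rng)
            tree = grow(X, y, MRTParams(minsplit=4, minbucket=2, cp=0.0))
            seq = prune_sequence(tree)
            cps = [cp for cp, _ in seq]
            sizes = [t.n_leaves for _, t in seq]
            errors = [t.relative_error for _, t in seq]
            assert cps == sorted(cps)
            assert sizes == sorted(sizes, reverse=True)
            assert errors == sorted(errors)  # error grows as the tree shrinks

    def test_pruning_pure_tree_at_cp_zero_is_identity(self):
        X = pd.DataFrame({"f": [0.1, 0.2, 5.0, 6.0]})
        y = encode_response(["a", "a", "b", "b"])
        tree = grow(X, y, MRTParams(minsplit=2, minbucket=1))
        seq = prune_sequence(tree)
        assert seq[0][0] == 0.0 and seq[0][1].n_leaves == tree.n_leaves

    def test_cv_error_nonnegative_and_deterministic(self, rng):
        X, y = self._dataset(rng)
        params = MRTParams(minsplit=4, minbucket=2, cp=0.0, xval=5, seed=3)
        _, t1 = cross_validate(X, y, params)
        _, t2 = cross_validate(X, y, params)
        pd.testing.assert_frame_equal(t1, t2)
        assert (t1["cv_error"] >= 0).all()

    def test_cv_zero_for_separable_data_at_true_size(self, ct_noiseless):
        ct, meta = ct_noiseless
        feat = ratio_features(relative_expression(ct))
        labels = meta.set_index("sample_id")["true_class"]
        full, table = cross_validate(feat.values, encode_response(labels), MRTParams(seed=0))
        row = table[table["n_leaves"] == 4]
        assert row["cv_error"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_fold_reduction_warning_for_small_classes(self, rng, caplog):
        import logging

        X = pd.DataFrame(rng.lognormal(size=(12, 2)))
        y = encode_response(["a"] * 8 + ["b"] * 4)
        with caplog.at_level(logging.WARNING, logger="pearlsex.mrt"):
            cross_validate(X, y, MRTParams(minsplit=4, xval=10, seed=0))
        assert any("folds" in r.message for r in caplog.records)


class TestSelectAndPartition:
    @pytest.fixture()
    def fitted(self, ct_default):
        ct, meta = ct_default
        feat = ratio_features(relative_expression(ct))
        labels = meta.set_index("sample_id")["true_class"]
        full, table = cross_validate(feat.values, encode_response(labels), MRTParams(seed=1))
        return full, table, feat, labels

    def test_min_cv_selects_four_leaves(self, fitted):
        full, table, *_ = fitted
        tree = select_tree(full, "min_cv")
        assert tree.n_leaves == 4
        assert tree.relative_error == pytest.approx(0.0)

    def test_fixed_leaves_one_returns_root(self, fitted):
        full, *_ = fitted
        tree = select_tree(full, "fixed_leaves", k_leaves=1)
        assert tree.n_leaves == 1 and tree.root.is_leaf

    def test_unavailable_size_lists_alternatives(self, fitted):
        full, *_ = fitted
        with pytest.raises(ValueError, match="available sizes"):
            select_tree(full, "fixed_leaves", k_leaves=99)

    def test_one_se_never_larger_than_min_cv(self, fitted):
        full, *_ = fitted
        assert select_tree(full, "one_se").n_leaves <= select_tree(full, "min_cv").n_leaves

    def test_variance_partition_sums_to_explained(self, fitted):
        full, table, *_ = fitted
        tree = select_tree(full, "min_cv")
        part = variance_partition(tree)
        assert part["percent_variance"].sum() == pytest.approx(
            100 * (1 - tree.relative_error), rel=1e-9
        )

    def test_root_only_partition_empty(self, fitted):
        full, *_ = fitted
        root = select_tree(full, "fixed_leaves", k_leaves=1)
        assert variance_partition(root).empty


class TestPredict:
    def test_resubstitution_reproduces_training_labels(self, ct_noiseless):
        ct, meta = ct_noiseless
        feat = ratio_features(relative_expression(ct))
        labels = meta.set_index("sample_id")["true_class"]
        tree = fit_mrt(feat.values, labels, MRTParams(seed=0))
        pred = predict(tree, feat.values)
        assert (pred == labels.reindex(pred.index)).all()

    def test_boundary_routes_right(self):
        X = pd.DataFrame({"f": [1.0, 1.0, 3.0, 3.0]})
        y = encode_response(["lo", "lo", "hi", "hi"])
        tree = grow(X, y, MRTParams(minsplit=2, minbucket=1))
        thr = tree.root.threshold
        at_boundary = pd.DataFrame({"f": [thr]})
        # value == threshold goes right (the >= side)
        assert predict(tree, at_boundary).iloc[0] == "hi"

    def test_missing_split_feature_errors(self):
        X = pd.DataFrame({"f": [0.1, 0.2, 5.0, 6.0]})
        y = encode_response(["a", "a", "b", "b"])
        tree = grow(X, y, MRTParams(minsplit=2, minbucket=1))
        with pytest.raises(ValueError, match="missing"):
            predict(tree, pd.DataFrame({"other": [1.0]}))

    def test_agrees_with_rule_classifier_on_grid(self):
        """A hand-built 4-leaf tree with the published thresholds routes
        exactly like the fixed 3-gene-pair rule classifier."""
        from pearlsex.mrt import MRTNode, MRTree
        from pearlsex.pathway import RuleSet, classify_pathway

        classes = ["MP", "FP", "eFP", "eMP"]

        def leaf(i, cls):
            mean = np.eye(4)[classes.index(cls)]
            return MRTNode(node_id=i, n=1, ss=0.0, mean=mean, sample_idx=np.array([0]))

        # r1 < 0.02 -> MP; else r2 >= 12.2 -> FP; else r3 >= 0.1 -> eFP else eMP
        n3 = MRTNode(
            node_id=3, n=2, ss=0.0, mean=np.zeros(4), sample_idx=np.array([0]),
            feature="foxl2/fem1-like", feature_idx=2, threshold=0.1,
            left=leaf(5, "eMP"), right=leaf(6, "eFP"),
        )
        n2 = MRTNode(
            node_id=2, n=3, ss=0.0, mean=np.zeros(4), sample_idx=np.array([0]),
            feature="foxl2/c54338", feature_idx=1, threshold=12.2,
            left=n3, right=leaf(4, "FP"),
        )
        root = MRTNode(
            node_id=0, n=4, ss=1.0, mean=np.full(4, 0.25), sample_idx=np.array([0]),
            feature="c43476/fem1-like", feature_idx=0, threshold=0.02,
            left=leaf(1, "MP"), right=n2,
        )
        tree = MRTree(
            root=root,
            feature_names=["c43476/fem1-like", "foxl2/c54338", "foxl2/fem1-like"],
            class_names=classes,
            ss_root=1.0,
            n=4,
            params=MRTParams(),
        )
        grid = np.array([1e-4, 1e-2, 0.02, 0.1, 1.0, 12.2, 1e2, 1e4])
        rules = RuleSet()
        rows, expected = [], []
        for r1, r2, r3 in itertools.product(grid, repeat=3):
            # both routes must see bit-identical ratios: build the feature
            # row from the same expression vector the classifier receives
            expr = pd.Series(
                {"fem1-like": 1.0, "c43476": r1, "c54338": r3 / r2, "foxl2": r3}
            )
            rows.append(
                {
                    "c43476/fem1-like": expr["c43476"] / expr["fem1-like"],
                    "foxl2/c54338": expr["foxl2"] / expr["c54338"],
                    "foxl2/fem1-like": expr["foxl2"] / expr["fem1-like"],
                }
            )
            expected.append(classify_pathway(expr, rules).predicted.value)
        preds = predict(tree, pd.DataFrame(rows))
        assert list(preds) == expected

    def test_agrees_with_rule_classifier_at_exact_boundaries(self):
        """Threshold-exact inputs route identically through rules and tree
        semantics: r1 = 0.02 is not MP, r2 = 12.2 is FP, r3 = 0.1 is eFP."""
        from pearlsex.pathway import RuleSet, classify_pathway

        rules = RuleSet()
        expr_r2 = pd.Series({"fem1-like": 1.0, "c43476": 1.0, "c54338": 1.0, "foxl2": 12.2})
        assert classify_pathway(expr_r2, rules).predicted.value == "FP"
        expr_r1 = pd.Series({"fem1-like": 1.0, "c43476": 0.02, "c54338": 1.0, "foxl2": 1.0})
        assert classify_pathway(expr_r1, rules).predicted.value != "MP"
        expr_r3 = pd.Series({"fem1-like": 1.0, "c43476": 1.0, "c54338": 1.0, "foxl2": 0.1})
        assert classify_pathway(expr_r3, rules).predicted.value == "eFP"


class TestRecovery:
    def test_designed_ratios_recovered_on_default_generator(self):
        """The selected tree uses exactly the three designed signature
        ratios with thresholds between the class design levels (subset of
        seeds; the full 100-seed rate is >= 95)."""
        from pearlsex.simulate import DESIGNED_RATIOS

        hits = 0
        for seed in range(10):
            ct, meta = simulate_ct(SimConfig(seed=seed))
            feat = ratio_features(relative_expression(ct))
            labels = meta.set_index("sample_id")["true_class"]
            tree = fit_mrt(feat.values, labels, MRTParams(seed=seed))
            if set(tree.split_features) == set(DESIGNED_RATIOS):
                hits += 1
                thr = {nd.feature: nd.threshold for nd in tree.root.internal()}
                assert 0.005 < thr["c43476/fem1-like"] < 0.2
                assert 2.0 < thr["foxl2/c54338"] < 50.0
                assert 0.01 < thr["foxl2/fem1-like"] < 1.0
        assert hits >= 9
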