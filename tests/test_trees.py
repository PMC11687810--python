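import math

import numpy as np
import pandas as pd
import pytest

from mirpanel.trees import (
    TreeParams, assign_groups, compare_groups, crossval_prune,
    evaluate_classifier, grow_classification_tree, grow_survival_tree,
)

SMALL = TreeParams(min_split=4, min_leaf=2)


class TestClassificationGrowth:
    def test_separable_single_split(self):
        X = pd.DataFrame({"x": np.concatenate([np.arange(-10, 0), np.arange(1, 11)])})
        y = ["other"] * 10 + ["case"] * 10
        tree = grow_classification_tree(X, y, SMALL)
        assert tree.root.feature == "x"
        m = evaluate_classifier(tree, X, y)
        assert m.accuracy == 1.0
        assert len(tree.root.leaves()) == 2

    def test_pure_input_single_leaf(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        tree = grow_classification_tree(X, ["case"] * 10, SMALL)
        assert tree.root.is_leaf

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            grow_classification_tree(pd.DataFrame({"x": []}), [])

    def test_root_split_matches_sklearn(self):
        """Gini root split (feature and threshold) agrees with an
        independent CART implementation."""
        from sklearn.tree import DecisionTreeClassifier

        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(0, 1, (80, 6)), columns=list("abcdef"))
            y = np.where(X["c"] + 0.8 * rng.normal(size=80) > 0, "case", "other")
            tree = grow_classification_tree(X, y, TreeParams())
            sk = DecisionTreeClassifier(
                criterion="gini", min_samples_split=20, min_samples_leaf=7,
                random_state=0,
            ).fit(X, y)
            assert tree.root.feature == X.columns[sk.tree_.feature[0]]
            # sklearn stores features as float32, so thresholds agree only to
            # single precision
            assert tree.root.threshold == pytest.approx(sk.tree_.threshold[0], abs=1e-6)

    def test_planted_diagnostic_structure(self, analyzed):
        """On the synthetic cohort the case-shifted miRNA heads the pruned
        diagnostic tree."""
        res, truth = analyzed
        values = res.normalized.non_control_values()
        by_id = {s.sample_id: s for s in res.samples}
        ids = [sid for sid in values.index]
        labels = [by_id[sid].group for sid in ids]
        tree = grow_classification_tree(values.loc[ids], labels, TreeParams())
        pruned, _ = crossval_prune(tree, values.loc[ids], labels=labels, seed=7)
        assert pruned.root.feature == "miR-214-3p"


class TestSurvivalGrowth:
    def test_two_rate_populations_split_on_marker(self):
        """Planted rates 1.0 vs 0.1 separated by a marker threshold: the tree
        splits on the marker and the leaf rate ratio is ~10."""
        rng = np.random.default_rng(0)
        n = 200
        marker = rng.normal(0, 1, n)
        fast = marker > 0
        lam = np.where(fast, 1.0, 0.1)
        t = rng.exponential(1 / lam)
        e = np.ones(n, int)
        X = pd.DataFrame({"marker": marker, "noise": rng.normal(0, 1, n)})
        tree = grow_survival_tree(X, t, e, TreeParams())
        assert tree.root.feature == "marker"
        left, right = tree.root.left, tree.root.right
        ratio = right.rate / left.rate
        assert ratio == pytest.approx(10.0, rel=0.3)

    def test_no_events_rejected(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValueError, match="event"):
            grow_survival_tree(X, np.arange(1, 11.0), np.zeros(10, int))

    def test_leaf_rate_ratio_vs_root(self):
        rng = np.random.default_rng(1)
        n = 100
        X = pd.DataFrame({"x": rng.normal(0, 1, n)})
        t = rng.exponential(100, n)
        e = np.ones(n, int)
        tree = grow_survival_tree(X, t, e, TreeParams(min_split=10, min_leaf=5))
        root_rate = e.sum() / t.sum()
        for leaf in tree.root.leaves():
            assert leaf.rate_ratio == pytest.approx(leaf.rate / root_rate)


class TestPruning:
    def test_root_only_tree_unchanged(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        tree = grow_classification_tree(X, ["case"] * 10, SMALL)
        pruned, trace = crossval_prune(tree, X, labels=["case"] * 10, k=5, seed=0)
        assert pruned.root.is_leaf
        assert len(trace.rows) == 1

    def test_sizes_strictly_decrease_and_pruned_is_subtree(self):
        rng = np.random.default_rng(3)
        n = 150
        X = pd.DataFrame(rng.normal(0, 1, (n, 5)), columns=list("abcde"))
        y = np.where(X["a"] + 0.5 * rng.normal(size=n) > 0, "case", "other")
        tree = grow_classification_tree(X, y, TreeParams())
        pruned, trace = crossval_prune(tree, X, labels=y, seed=1)
        sizes = [r["size"] for r in trace.rows]
        assert all(s1 > s2 for s1, s2 in zip(sizes, sizes[1:]))
        assert pruned.root.node_ids() <= tree.root.node_ids()
        # resubstitution accuracy never increases under pruning
        resub = [r["resub_error"] for r in trace.rows]
        assert all(r2 >= r1 - 1e-12 for r1, r2 in zip(resub, resub[1:]))

    def test_chosen_cp_attains_min_cv_error(self):
        rng = np.random.default_rng(4)
        n = 120
        X = pd.DataFrame(rng.normal(0, 1, (n, 4)), columns=list("abcd"))
        y = np.where(X["a"] > 0, "case", "other")
        tree = grow_classification_tree(X, y, TreeParams())
        pruned, trace = crossval_prune(tree, X, labels=y, seed=2)
        errs = [r["cv_error"] for r in trace.rows]
        chosen = [r for r in trace.rows if r["cp"] == trace.chosen_cp]
        assert chosen[0]["cv_error"] == pytest.approx(min(errs))

    def test_noise_only_survival_trees_mostly_collapse(self):
        """Under a pure-noise covariate set, cross-validated pruning takes
        the tree back to its root in most replicates."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 61
            t = rng.exponential(300, n)
            c = rng.exponential(1200, n)
            tt, e = np.ceil(np.minimum(t, c)), (t <= c).astype(int)
            X = pd.DataFrame(rng.normal(0, 0.8, (n, 36)),
                             columns=[f"m{i}" for i in range(36)])
            tree = grow_survival_tree(X, tt, e, TreeParams())
            pruned, _ = crossval_prune(tree, X, time=tt, event=e, seed=seed)
            wins += pruned.root.is_leaf
        assert wins >= 7

    def test_null_pruning_rate_comparable_to_rpart(self, tmp_path):
        """On identical null survival datasets, this implementation and R's
        rpart (method='exp', same growth controls, min-xerror pruning) both
        collapse most trees to the root."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        n_sets = 12
        ours = 0
        for seed in range(n_sets):
            rng = np.random.default_rng(seed)
            n = 61
            t = rng.exponential(300, n)
            c = rng.exponential(1200, n)
            tt, e = np.ceil(np.minimum(t, c)), (t <= c).astype(int)
            X = pd.DataFrame(rng.normal(0, 0.8, (n, 20)),
                             columns=[f"x{i}" for i in range(20)])
            tree = grow_survival_tree(X, tt, e, TreeParams())
            pruned, _ = crossval_prune(tree, X, time=tt, event=e, seed=seed)
            ours += pruned.root.is_leaf
            out = X.copy()
            out.insert(0, "time", tt)
            out.insert(1, "event", e)
            out.to_csv(tmp_path / f"null_{seed}.csv", index=False)
        rscript = tmp_path / "check.R"
        rscript.write_text(
            "suppressMessages({library(survival); library(rpart)})\n"
            "root_only <- 0\n"
            f"for (seed in 0:{n_sets - 1}) {{\n"
            "  d <- read.csv(sprintf('" + str(tmp_path) + "/null_%d.csv', seed))\n"
            "  set.seed(seed)\n"
            "  fit <- rpart(Surv(time, event) ~ ., data = d, method = 'exp',\n"
            "               control = rpart.control(cp = 0.01, minsplit = 20,\n"
            "                                       minbucket = 7, xval = 10))\n"
            "  cpt <- fit$cptable\n"
            "  pr <- prune(fit, cp = cpt[which.min(cpt[, 'xerror']), 'CP'])\n"
            "  if (sum(pr$frame$var == '<leaf>') == 1) root_only <- root_only + 1\n"
            "}\n"
            "cat(root_only, '\\n')\n"
        )
        proc = subprocess.run(["Rscript", "--vanilla", str(rscript)],
                              capture_output=True, text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        theirs = int(proc.stdout.strip().split()[-1])
        assert ours >= 8
        assert theirs >= 8

    def test_k_exceeding_n_rejected(self):
        X = pd.DataFrame({"x": np.arange(5.0)})
        tree = grow_classification_tree(X, ["case", "other"] * 2 + ["case"], SMALL)
        with pytest.raises(ValueError, match="folds"):
            crossval_prune(tree, X, labels=["case", "other"] * 2 + ["case"], k=10)


class TestEvaluation:
    def fit_threshold_tree(self):
        """A tree predicting case for x > 0 with leaf probabilities < 1."""
        X = pd.DataFrame({"x": np.concatenate([
            -np.arange(1, 13.0), np.arange(1, 15.0)])})
        y = (["other"] * 10 + ["case"] * 2) + (["case"] * 12 + ["other"] * 2)
        return grow_classification_tree(X, y, TreeParams(min_split=4, min_leaf=3))

    def test_perfect_classifier_metrics(self):
        X = pd.DataFrame({"x": np.concatenate([-np.arange(1, 11.0), np.arange(1, 11.0)])})
        y = ["other"] * 10 + ["case"] * 10
        tree = grow_classification_tree(X, y, SMALL)
        m = evaluate_classifier(tree, X, y)
        assert (m.accuracy, m.precision, m.recall, m.auc) == (1, 1, 1, 1)

    def test_constant_classifier_auc_half(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        tree = grow_classification_tree(X, ["case"] * 10, SMALL)
        test_X = pd.DataFrame({"x": np.arange(8.0)})
        m = evaluate_classifier(tree, test_X, ["case"] * 4 + ["other"] * 4)
        assert m.auc == 0.5

    def test_confusion_arithmetic(self):
        """Confusion (TP 12, FN 1, FP 2, TN 2): accuracy 14/17, recall 12/13,
        precision 12/14."""
        tree = self.fit_threshold_tree()
        assert tree.root.feature == "x"
        thr = tree.root.threshold
        x_test = ([thr + 1] * 12 + [thr - 1]          # 12 TP, 1 FN
                  + [thr + 1] * 2 + [thr - 1] * 2)    # 2 FP, 2 TN
        y_test = ["case"] * 13 + ["other"] * 4
        m = evaluate_classifier(tree, pd.DataFrame({"x": x_test}), y_test)
        assert (m.tp, m.fn, m.fp, m.tn) == (12, 1, 2, 2)
        assert m.accuracy == pytest.approx(14 / 17)
        assert round(m.accuracy, 3) == 0.824
        assert m.recall == pytest.approx(12 / 13)
        assert round(m.recall, 3) == 0.923
        assert m.precision == pytest.approx(12 / 14)
        assert round(m.precision, 3) == 0.857

    def test_single_class_test_set_auc_undefined(self):
        tree = self.fit_threshold_tree()
        m = evaluate_classifier(tree, pd.DataFrame({"x": [1.0, 2.0]}),
                                ["case", "case"])
        assert math.isnan(m.auc)
        assert m.recall == 1.0


class TestGroups:
    def test_single_leaf_single_group(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        tree = grow_classification_tree(X, ["case"] * 10, SMALL)
        groups = assign_groups(tree, X)
        assert groups.nunique() == 1

    def test_routing_deterministic(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(0, 1, (50, 3)), columns=list("abc"))
        y = np.where(X["a"] > 0, "case", "other")
        tree = grow_classification_tree(X, y, SMALL)
        g1 = assign_groups(tree, X)
        g2 = assign_groups(tree, X)
        pd.testing.assert_series_equal(g1, g2)

    def test_four_groups_six_adjusted_pairs(self):
        rng = np.random.default_rng(6)
        n = 120
        labels = pd.Series([f"node{i % 4}" for i in range(n)])
        t = rng.exponential(100, n)
        e = np.ones(n, int)
        comp = compare_groups(labels, t, e)
        assert len(comp["pairwise"]) == 6
        for row in comp["pairwise"].itertuples(index=False):
            assert row.adjusted_p == pytest.approx(min(1.0, row.raw_p * 6))

    def test_planted_two_group_hazard_detected(self):
        rng = np.random.default_rng(7)
        n = 100
        g = np.array(["node1"] * 50 + ["node2"] * 50)
        lam = np.where(g == "node1", 0.01, 0.03)
        t = rng.exponential(1 / lam)
        e = np.ones(n, int)
        comp = compare_groups(pd.Series(g), t, e, use_cox=True)
        row = comp["pairwise"].iloc[0]
        assert row["adjusted_p"] < 0.05
        assert row["hr"] == pytest.approx(3.0, rel=0.5)

    def test_hemolysis_affected_markers_never_in_prognostic_tree(self, analyzed):
        """Prognostic features are restricted to hemolysis-unaffected assays,
        so planted coupled markers cannot enter the survival tree."""
        res, truth = analyzed
        safe = res.safe_assays()
        for coupled in truth.hemolysis_coupled:
            assert coupled not in safe
        ids = res.case_ids()
        t, e, kept = res.endpoint(ids, "os")
        X = res.normalized.non_control_values().loc[kept, safe]
        tree = grow_survival_tree(X, t, e, TreeParams())
        features = {n.feature for n in tree.root.internal()}
        assert features.isdisjoint(truth.hemolysis_coupled)
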