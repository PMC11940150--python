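"""Metrics arithmetic, BCa bootstrap, group importance, tallies,
misclassification tests, and forest proximity."""

import numpy as np
import pandas as pd
import pytest

from parkisense.evaluation import (
    BootstrapConfig,
    ConfusionMatrix,
    auc_mann_whitney,
    bca_bootstrap_ci,
    compute_metrics,
    forest_proximity,
    group_permutation_importance,
    misclassification_comparison,
    proximity_nearest_class,
    selection_tally,
)
from parkisense.features import TablePreprocessor
from parkisense.miee import CVConfig, MIEE, MieeConfig, cross_validate

from conftest import make_gaussian_table


class TestMetrics:
    def test_agrees_with_sklearn_on_random_labels(self):
        from sklearn.metrics import balanced_accuracy_score, f1_score, recall_score

        rng = np.random.default_rng(0)
        true = rng.choice(["pd", "nonpd"], 200, p=[0.85, 0.15])
        pred = rng.choice(["pd", "nonpd"], 200, p=[0.8, 0.2])
        cm = ConfusionMatrix.from_labels(true, pred, "pd")
        m = compute_metrics(cm)
        assert m["balanced_accuracy"] == pytest.approx(
            balanced_accuracy_score(true, pred)
        )
        assert m["sensitivity"] == pytest.approx(
            recall_score(true, pred, pos_label="pd")
        )
        assert m["f1"] == pytest.approx(f1_score(true, pred, pos_label="pd"))

    def test_perfect_predictions(self):
        m = compute_metrics(
            ConfusionMatrix(tp=10, fn=0, fp=0, tn=5),
            probabilities=np.r_[np.zeros(10), np.ones(5)],
            true_labels=np.array(["pd"] * 10 + ["nonpd"] * 5),
            positive="pd",
        )
        assert all(v == 1.0 for v in m.values())

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix(tp=5, fn=5, fp=0, tn=0))

    def test_auc_equals_brute_force_mann_whitney(self):
        rng = np.random.default_rng(1)
        pos = rng.random(13)
        neg = rng.random(7)
        pos[3] = neg[2]  # force a tie
        brute = np.mean(
            [(1.0 if a > b else 0.5 if a == b else 0.0) for a in pos for b in neg]
        )
        assert auc_mann_whitney(pos, neg) == pytest.approx(brute)

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 100)
        s = rng.random(100)
        assert auc_mann_whitney(s[y == 1], s[y == 0]) == pytest.approx(
            roc_auc_score(y, s)
        )


class TestBcaBootstrap:
    def test_constant_metric_zero_width(self):
        out = np.ones(30)
        lo, hi, flag = bca_bootstrap_ci(
            [out, np.ones(10)],
            lambda a, b: 0.5 * (a.mean() + b.mean()),
            BootstrapConfig(n_replicates=200, seed=0),
        )
        assert lo == hi == 1.0

    def test_interval_bounds_and_ordering(self):
        rng = np.random.default_rng(3)
        a = (rng.random(60) < 0.8).astype(float)
        b = (rng.random(20) < 0.6).astype(float)
        metric = lambda x, y: 0.5 * (x.mean() + y.mean())
        lo, hi, flag = bca_bootstrap_ci([a, b], metric, BootstrapConfig(1000, seed=1))
        point = metric(a, b)
        assert 0.0 <= lo <= point <= hi <= 1.0

    def test_balanced_resampling_preserves_class_sizes(self):
        sizes = []

        def metric(a, b):
            sizes.append((len(a), len(b)))
            return a.mean() + b.mean()

        rng = np.random.default_rng(4)
        bca_bootstrap_ci(
            [rng.random(25), rng.random(9)], metric, BootstrapConfig(100, seed=2)
        )
        # every bootstrap resample keeps the original per-class sizes; the
        # only other calls are the BCa jackknife leave-one-out evaluations
        jackknife = {(24, 9), (25, 8)}
        assert {(25, 9)} <= set(sizes) <= {(25, 9)} | jackknife


class TestGroupImportance:
    def fit(self, n_signal=4):
        table, y = make_gaussian_table(
            n=60, p=60, n_minority=12, n_signal=n_signal, shift=2.5, seed=20
        )
        # relabel half the columns as a second task group with no signal
        meta = table.metadata.copy()
        meta.iloc[30:, meta.columns.get_loc("task")] = "walk32ft"
        table.metadata = meta
        train = np.r_[0:36, 48:54]
        test = np.setdiff1d(np.arange(60), train)
        prep = TablePreprocessor().fit(table, train)
        res = MIEE(
            prep.transform(table, np.arange(60)).iloc[train], y[train],
            MieeConfig(n_trees=50, seed=3),
        ).fit()
        X_test = prep.transform(table, test)
        groups = {t: g.index.tolist() for t, g in meta.groupby("task")}
        return res, X_test, y[test], groups

    def test_signal_group_ranks_first_and_empty_group_zero(self):
        res, X_test, y_test, groups = self.fit()
        groups["stand_eo_20s"] = []  # group with no features in the model
        imp = group_permutation_importance(res, X_test, y_test, groups,
                                           n_permutations=20, seed=5)
        assert imp.index[0] == "tug"
        assert imp["stand_eo_20s"] == 0.0

    def test_invariant_to_feature_order_within_group(self):
        res, X_test, y_test, groups = self.fit()
        imp1 = group_permutation_importance(res, X_test, y_test, groups,
                                            n_permutations=10, seed=6)
        groups_rev = {g: list(reversed(cols)) for g, cols in groups.items()}
        imp2 = group_permutation_importance(res, X_test, y_test, groups_rev,
                                            n_permutations=10, seed=6)
        pd.testing.assert_series_equal(imp1, imp2)

    def test_unmapped_feature_rejected(self):
        res, X_test, y_test, groups = self.fit()
        bad = {g: cols[:1] for g, cols in groups.items()}
        with pytest.raises(ValueError, match="not mapped"):
            group_permutation_importance(res, X_test, y_test, bad, n_permutations=2)

    def test_permuting_everything_drops_to_chance(self):
        res, X_test, y_test, groups = self.fit()
        rng = np.random.default_rng(7)
        baccs = []
        from parkisense.evaluation import ConfusionMatrix, compute_metrics

        for _ in range(30):
            Xp = X_test.copy()
            Xp[:] = X_test.to_numpy()[rng.permutation(len(X_test))]
            cm = ConfusionMatrix.from_labels(
                y_test, res.predict(Xp), res.model.majority_label
            )
            baccs.append(compute_metrics(cm)["balanced_accuracy"])
        assert np.mean(baccs) == pytest.approx(0.5, abs=0.12)


class TestSelectionTally:
    def test_fractions_sum_to_one_and_planted_signal_dominates(self, small_table, small_labels):
        cv = cross_validate(
            small_table, small_labels, CVConfig(n_repeats=1, seed=8),
            MieeConfig(n_trees=30, seed=8),
        )
        tal = selection_tally(cv, small_table.metadata)
        for key in ("task", "subtask", "derivation"):
            assert tal[key].sum() == pytest.approx(1.0)
        # class effects were restricted to the TUG task in this cohort
        assert tal["task"].idxmax() == "tug"
        assert tal["task"]["tug"] > 0.5

    def test_single_task_selection_fraction_is_one(self):
        table, y = make_gaussian_table(n=45, n_minority=9, seed=21)
        cv = cross_validate(table, y, CVConfig(n_repeats=1, seed=9),
                            MieeConfig(n_trees=20, seed=9))
        tal = selection_tally(cv, table.metadata)
        assert tal["task"].to_dict() == {"tug": pytest.approx(1.0)}


class TestMisclassification:
    def test_identical_groups_t_statistic_zero(self):
        final = np.array(["pd"] * 10 + ["nonpd"] * 10)
        true = np.array(["pd"] * 20)
        cov = pd.DataFrame({"age": np.r_[np.arange(10), np.arange(10)].astype(float)})
        out = misclassification_comparison(final, true, cov)
        row = out[(out["class"] == "pd") & (out["covariate"] == "age")].iloc[0]
        assert row["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_t_statistic_matches_textbook_formula(self):
        rng = np.random.default_rng(22)
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 50)
        final = np.array(["pd"] * 50 + ["nonpd"] * 50)
        true = np.array(["pd"] * 100)
        cov = pd.DataFrame({"x": np.r_[a, b]})
        out = misclassification_comparison(final, true, cov)
        t = out.iloc[0]["statistic"]
        sp2 = ((49 * a.var(ddof=1)) + (49 * b.var(ddof=1))) / 98
        expect = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 50 + 1 / 50))
        assert t == pytest.approx(expect, abs=1e-9)

    def test_chi2_diagonal_table_is_20(self):
        # 2x2 table (10,0;0,10) without continuity correction
        final = np.array(["pd"] * 10 + ["nonpd"] * 10)
        true = np.array(["pd"] * 20)
        cov = pd.DataFrame({"sex": ["m"] * 10 + ["f"] * 10})
        out = misclassification_comparison(final, true, cov, categorical=("sex",))
        assert out.iloc[0]["statistic"] == pytest.approx(20.0)

    def test_small_group_flagged(self):
        final = np.array(["pd"] * 19 + ["nonpd"])
        true = np.array(["pd"] * 20)
        cov = pd.DataFrame({"age": np.arange(20.0)})
        out = misclassification_comparison(final, true, cov)
        assert out.iloc[0]["flag"] == "group-too-small"


class TestProximity:
    def test_proximity_symmetric_bounded_and_duplicate_is_one(self):
        from sklearn.ensemble import RandomForestClassifier

        rng = np.random.default_rng(23)
        X = rng.standard_normal((40, 5))
        y = (X[:, 0] > 0).astype(int)
        forest = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, y)
        P = forest_proximity(forest, X[:10], X[:10])
        assert np.all((P >= 0) & (P <= 1))
        np.testing.assert_allclose(P, P.T)
        np.testing.assert_allclose(np.diag(P), 1.0)

    def test_three_cluster_nearest_class_agrees_with_centroids(self):
        rng = np.random.default_rng(24)
        centers = np.array([[0, 0], [6, 0], [0, 6]], dtype=float)
        subtype_names = np.array(["msa", "psp", "dlb"])
        X_min = np.vstack([c + 0.4 * rng.standard_normal((8, 2)) for c in centers])
        subtypes = np.repeat(subtype_names, 8)
        X_query = np.vstack([c + 0.4 * rng.standard_normal((5, 2)) for c in centers])
        true_nearest = np.repeat(subtype_names, 5)

        cols = ["tug.trial1.walk1.acc_v.f0", "tug.trial1.walk1.acc_v.f1"]
        Xq = pd.DataFrame(X_query, columns=cols)
        Xm = pd.DataFrame(X_min, columns=cols)
        # majority blob sits between the clusters, so the class boundary has
        # to wrap each minority cluster separately
        X_maj = np.array([2.0, 2.0]) + 0.6 * rng.standard_normal((24, 2))
        table_vals = pd.DataFrame(np.vstack([X_maj, X_min]), columns=cols)
        y = np.array(["pd"] * 24 + ["nonpd"] * 24)
        res = MIEE(table_vals, y, MieeConfig(top_k=2, n_trees=60, seed=4)).fit()
        out = proximity_nearest_class(res, Xq, Xm, subtypes)
        agree = (out["nearest_subtype"].to_numpy() == true_nearest).mean()
        assert agree >= 0.8

    def test_empty_minority_rejected(self):
        table, y = make_gaussian_table(seed=25)
        res = MIEE(table.values, y, MieeConfig(n_trees=10, seed=5)).fit()
        with pytest.raises(ValueError, match="empty"):
            proximity_nearest_class(
                res, table.values.iloc[:2], table.values.iloc[:0], np.array([])
            )
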