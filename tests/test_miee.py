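"""MIEE: mutual information, balanced subsets, ensemble training,
cross-validation, leakage audit, held-out scoring."""

import numpy as np
import pandas as pd
import pytest

from parkisense.miee import (
    CVConfig,
    MIEE,
    MieeConfig,
    build_balanced_subsets,
    cross_validate,
    mutual_information_scores,
    predict_held_out,
)
from parkisense.features import TablePreprocessor

from conftest import make_gaussian_table


class TestMutualInformation:
    def test_duplicate_balanced_label_is_ln2(self):
        y = np.array([0] * 12 + [1] * 12)
        mi = mutual_information_scores(y.astype(float), y)
        assert mi[0] == pytest.approx(np.log(2), abs=0.05)

    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 25 + [1] * 25)
        mis = [
            mutual_information_scores(rng.standard_normal(50), y, seed=i)[0]
            for i in range(50)
        ]
        assert np.mean(mis) < 0.08  # estimator bias band around 0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        y = np.array([0] * 40 + [1] * 40)
        x = rng.standard_normal(80) + 1.2 * y
        mi_x = mutual_information_scores(x, y, seed=3)[0]
        mi_t = mutual_information_scores(np.exp(x / 2), y, seed=3)[0]
        assert mi_t == pytest.approx(mi_x, abs=0.12)

    def test_matches_sklearn_estimator(self):
        # independent route: sklearn's per-feature KSG implementation
        from sklearn.feature_selection import mutual_info_classif

        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 100)
        X = rng.standard_normal((100, 15))
        X[:, 0] += 1.5 * y
        mine = mutual_information_scores(X, y, seed=11)
        skl = mutual_info_classif(X, y, n_neighbors=3, random_state=11)
        np.testing.assert_allclose(mine, skl, atol=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mutual_information_scores(np.ones(10), np.zeros(10))

    def test_nonnegative(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 30)
        mi = mutual_information_scores(rng.standard_normal((30, 50)), y)
        assert (mi >= 0).all()


class TestBalancedSubsets:
    def test_default_fold_arithmetic(self):
        # a training fold of the default cohort: 173 majority, 12 minority
        labels = np.array(["pd"] * 173 + ["nonpd"] * 12)
        subsets = build_balanced_subsets(labels, MieeConfig(), seed=0)
        assert len(subsets) == 5
        for rows in subsets:
            assert len(rows) == 24
            vals, counts = np.unique(labels[rows], return_counts=True)
            assert dict(zip(vals, counts)) == {"pd": 12, "nonpd": 12}

    def test_equal_classes_full_sample(self):
        labels = np.array(["a"] * 10 + ["b"] * 10)
        for rows in build_balanced_subsets(labels, MieeConfig(n_subsets=3), seed=1):
            assert len(rows) == 20

    def test_same_seed_identical_draws_different_subsets_differ(self):
        labels = np.array(["pd"] * 50 + ["nonpd"] * 8)
        s1 = build_balanced_subsets(labels, seed=9)
        s2 = build_balanced_subsets(labels, seed=9)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a, b)
        assert any(not np.array_equal(s1[0], s) for s in s1[1:])

    def test_swap_warning_for_wrong_nominal_minority(self):
        labels = np.array(["pd"] * 5 + ["nonpd"] * 15)
        with pytest.warns(UserWarning, match="swapping"):
            build_balanced_subsets(labels, seed=0, minority="nonpd")


class TestModelFit:
    def test_exactly_n_subsets_members_and_seed_determinism(self):
        table, y = make_gaussian_table(seed=5)
        cfg = MieeConfig(n_trees=50, seed=3)
        r1 = MIEE(table.values, y, cfg).fit()
        r2 = MIEE(table.values, y, cfg).fit()
        assert len(r1.members) == 5
        for m1, m2 in zip(r1.members, r2.members):
            assert m1.features == m2.features

    def test_signal_features_selected_across_subsets(self):
        table, y = make_gaussian_table(n=80, p=400, n_minority=16, n_signal=5,
                                       shift=2.5, seed=6)
        res = MIEE(table.values, y, MieeConfig(n_trees=50, seed=1)).fit()
        signal = {f"tug.trial1.walk1.acc_v.f{j}" for j in range(5)}
        hits = sum(bool(signal & set(mem.features)) for mem in res.members)
        assert hits >= 4

    def test_top_k_larger_than_feature_count_warns_and_uses_all(self):
        table, y = make_gaussian_table(p=10, seed=7)
        with pytest.warns(UserWarning, match="using all"):
            res = MIEE(table.values, y, MieeConfig(top_k=30, n_trees=20, seed=0)).fit()
        assert all(len(m.features) == 10 for m in res.members)

    def test_probability_averaging_contract(self):
        table, y = make_gaussian_table(seed=8)
        res = MIEE(table.values, y, MieeConfig(n_trees=20, seed=2)).fit()

        class Fixed:
            def __init__(self, p, classes):
                self.p = p
                self.classes_ = classes

            def predict_proba(self, X):
                return np.column_stack(
                    [np.full(len(X), 1 - self.p), np.full(len(X), self.p)]
                )

        classes = np.array(["nonpd", "pd"])  # minority first column? -> index below
        for p_members, expected in (
            ((1.0, 1.0, 1.0, 1.0, 1.0), 1.0),
            ((0.2, 0.4, 0.6, 0.8, 1.0), 0.6),
        ):
            for mem, p in zip(res.members, p_members):
                mem.forest = Fixed(p, np.array(["pd", "nonpd"]))
                # Fixed puts P(nonpd)=p in column matching classes_ order
                mem.forest.predict_proba = (
                    lambda X, p=p: np.column_stack(
                        [np.full(len(X), 1 - p), np.full(len(X), p)]
                    )
                )
            probs = res.predict_probability(table.values.iloc[:3])
            assert probs == pytest.approx(expected)
            assert np.all((probs >= 0) & (probs <= 1))

    def test_save_load_round_trip_preserves_predictions(self, tmp_path):
        from parkisense.miee import MIEEResults

        table, y = make_gaussian_table(seed=14)
        res = MIEE(table.values, y, MieeConfig(n_trees=20, seed=8)).fit()
        res.save(tmp_path / "model.joblib")
        back = MIEEResults.load(tmp_path / "model.joblib")
        np.testing.assert_array_equal(
            back.predict_probability(table.values),
            res.predict_probability(table.values),
        )
        assert [m.features for m in back.members] == [m.features for m in res.members]

    def test_unknown_columns_rejected_at_prediction(self):
        table, y = make_gaussian_table(seed=9)
        res = MIEE(table.values, y, MieeConfig(n_trees=20, seed=2)).fit()
        bad = table.values.iloc[:2, :5]
        with pytest.raises(KeyError, match="unknown feature columns"):
            res.predict_probability(bad)


class TestCrossValidation:
    def test_each_participant_scored_once_per_repeat(self):
        table, y = make_gaussian_table(n=45, n_minority=9, seed=10)
        cv = cross_validate(table, y, CVConfig(n_repeats=3, seed=4),
                            MieeConfig(n_trees=20, seed=4))
        assert cv.probabilities.shape == (3, 45)
        assert np.isfinite(cv.probabilities).all()
        for r in range(3):
            assert set(cv.fold_of[r]) == {0, 1, 2}

    def test_majority_vote(self):
        table, y = make_gaussian_table(n=45, n_minority=9, seed=11)
        cv = cross_validate(table, y, CVConfig(n_repeats=3, seed=5),
                            MieeConfig(n_trees=20, seed=5))
        votes = (cv.repeat_labels == cv.minority_label).sum(axis=0)
        expect = np.where(votes > 1.5, cv.minority_label, "pd")
        np.testing.assert_array_equal(cv.final_labels, expect)

    def test_even_repeats_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            CVConfig(n_repeats=4)

    def test_no_leakage_training_is_bit_identical_without_test_rows(self):
        table, y = make_gaussian_table(n=60, n_minority=12, seed=12)
        train_rows = np.r_[0:32, 48:56]  # 32 majority + 8 minority
        test_rows = np.setdiff1d(np.arange(60), train_rows)
        cfg = MieeConfig(n_trees=30, seed=6)

        prep_full = TablePreprocessor().fit(table, train_rows)
        res_full = MIEE(prep_full.transform(table, train_rows), y[train_rows], cfg).fit()

        from parkisense.features import FeatureTable

        truncated = FeatureTable(table.values.iloc[train_rows], table.metadata)
        prep_trunc = TablePreprocessor().fit(truncated, np.arange(len(train_rows)))
        res_trunc = MIEE(
            prep_trunc.transform(truncated, np.arange(len(train_rows))),
            y[train_rows], cfg,
        ).fit()

        assert prep_full.kept_columns == prep_trunc.kept_columns
        np.testing.assert_array_equal(prep_full.medians_, prep_trunc.medians_)
        for m1, m2 in zip(res_full.members, res_trunc.members):
            assert m1.features == m2.features
        X_test = prep_full.transform(table, test_rows)
        np.testing.assert_array_equal(
            res_full.predict_probability(X_test), res_trunc.predict_probability(X_test)
        )


class TestHeldOut:
    def fit_reference(self):
        table, y = make_gaussian_table(n=62, n_minority=14, seed=13)
        train = np.arange(56)
        held = np.arange(56, 62)
        prep = TablePreprocessor().fit(table, train)
        res = MIEE(prep.transform(table, train), y[train], MieeConfig(n_trees=30, seed=7)).fit()
        ref_probs = res.predict_probability(prep.transform(table, train))
        ref_labels = np.where(ref_probs >= 0.5, "nonpd", "pd")
        return table, y, train, held, prep, res, ref_probs, ref_labels

    def test_probabilities_and_percentiles(self):
        table, y, train, held, prep, res, ref_probs, ref_labels = self.fit_reference()
        out = predict_held_out(res, prep, table, held, ref_probs, ref_labels)
        assert len(out) == len(held)
        assert ((out["probability"] >= 0) & (out["probability"] <= 1)).all()
        assert ((out["percentile"] >= 0) & (out["percentile"] <= 100)).all()

    def test_maximum_score_gets_percentile_100(self):
        table, y, train, held, prep, res, ref_probs, ref_labels = self.fit_reference()
        big = ref_probs.max()
        out = predict_held_out(
            res, prep, table, held[:1],
            np.append(ref_probs, 0.0), np.append(ref_labels, "pd"),
        )
        row = out.iloc[0]
        same = np.append(ref_probs, 0.0)[np.append(ref_labels, "pd") == row["label"]]
        if row["probability"] >= same.max():
            assert row["percentile"] == 100.0

    def test_single_member_reference_flagged(self):
        table, y, train, held, prep, res, ref_probs, ref_labels = self.fit_reference()
        out = predict_held_out(
            res, prep, table, held[:1], np.array([0.9]), np.array([ref_labels[0]])
        )
        row = out.iloc[0]
        if row["label"] == ref_labels[0]:
            assert row["percentile"] == 100.0
            assert row["flag"] == "single-member-reference-class"
        else:
            assert row["flag"] == "empty-reference-class"

    def test_duplicated_training_row_scores_close_to_in_sample(self):
        table, y, train, held, prep, res, ref_probs, ref_labels = self.fit_reference()
        Xtr = prep.transform(table, train)
        minority_rows = np.flatnonzero(y[train] == "nonpd")
        dup = Xtr.iloc[[minority_rows[0]]]
        p_dup = res.predict_probability(dup)[0]
        assert p_dup >= ref_probs[minority_rows[0]] - 0.1
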