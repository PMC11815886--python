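"""Ensemble classifier: binarization, training, CV, metrics, importance."""

import numpy as np
import pytest

import pairclass as pc
from pairclass.exceptions import GeneLookupError, ValidationError

from conftest import monotone_transform


class TestBinarize:
    def test_feature_count_and_ids(self, small_cohort, small_features):
        fm = pc.binarize(small_cohort.expression, small_features)
        n_expected = small_features.n_pairs()
        assert len(fm.feature_ids) == n_expected
        assert fm.values.shape == (len(small_cohort.expression.sample_ids), n_expected)
        assert all(":" in f and "<" in f for f in fm.feature_ids)

    def test_ties_score_zero(self):
        expr = pc.ExpressionMatrix(["A", "B"], ["s1", "s2"], np.array([[2.0, 1.0], [2.0, 3.0]]))
        fm = pc.binarize(expr, pc.FeatureSet({"c1": [("A", "B")]}))
        assert list(fm.values[:, 0]) == [0, 1]

    def test_monotone_view_gives_identical_features(self, small_cohort, small_features):
        rng = np.random.default_rng(1)
        view = pc.ExpressionMatrix(
            list(small_cohort.expression.gene_ids),
            list(small_cohort.expression.sample_ids),
            monotone_transform(small_cohort.expression.values, rng),
        )
        a = pc.binarize(small_cohort.expression, small_features)
        b = pc.binarize(view, small_features)
        assert np.array_equal(a.values, b.values)

    def test_missing_gene_policies(self, small_cohort):
        genes = small_cohort.expression.gene_ids
        # 4-pair cluster: dropping one pair stays within the 25% cap
        fs = pc.FeatureSet(
            {"cx": [(genes[i], genes[i + 1]) for i in range(0, 8, 2)]}
        )
        keep = [g for g in genes if g != genes[0]]
        idx = [small_cohort.expression.gene_position(g) for g in keep]
        reduced = pc.ExpressionMatrix(
            keep, list(small_cohort.expression.sample_ids),
            small_cohort.expression.values[idx],
        )
        with pytest.raises(GeneLookupError):
            pc.binarize(reduced, fs)
        fm = pc.binarize(reduced, fs, missing="drop")
        assert len(fm.feature_ids) == 3

    def test_drop_cap_refuses_gutted_cluster(self, small_cohort, small_features):
        cluster = small_features.clusters[0]
        victims = {p[0] for p in small_features.pairs[cluster][:2]}
        keep = [g for g in small_cohort.expression.gene_ids if g not in victims]
        idx = [small_cohort.expression.gene_position(g) for g in keep]
        reduced = pc.ExpressionMatrix(
            keep, list(small_cohort.expression.sample_ids),
            small_cohort.expression.values[idx],
        )
        with pytest.raises(ValidationError, match="25%"):
            pc.binarize(reduced, small_features, missing="drop")


class TestTrainPredict:
    def test_separable_cohort_fits_training_set(self, small_cohort, small_features):
        fm = pc.binarize(small_cohort.expression, small_features)
        model = pc.train(fm, small_cohort.labels, pc.ModelParams(seed=1))
        preds = pc.predict(model, small_cohort.expression)
        truth = small_cohort.labels.assignments
        acc = np.mean([truth[s] == c for s, c in zip(preds.sample_ids, preds.best_calls)])
        assert acc == 1.0

    def test_determinism_single_learner(self, small_cohort, small_features):
        fm = pc.binarize(small_cohort.expression, small_features)
        params = pc.ModelParams(ensemble_size=1, subsample_fraction=1.0, seed=7)
        p1 = pc.predict(pc.train(fm, small_cohort.labels, params), small_cohort.expression)
        p2 = pc.predict(pc.train(fm, small_cohort.labels, params), small_cohort.expression)
        assert p1.best_calls == p2.best_calls
        assert np.array_equal(p1.scores, p2.scores)

    def test_monotone_view_predicts_identically(self, small_cohort, small_features):
        fm = pc.binarize(small_cohort.expression, small_features)
        model = pc.train(fm, small_cohort.labels, pc.ModelParams(seed=2))
        rng = np.random.default_rng(3)
        view = pc.ExpressionMatrix(
            list(small_cohort.expression.gene_ids),
            list(small_cohort.expression.sample_ids),
            monotone_transform(small_cohort.expression.values, rng),
        )
        a = pc.predict(model, small_cohort.expression)
        b = pc.predict(model, view)
        assert a.best_calls == b.best_calls
        assert np.array_equal(a.scores, b.scores)

    def test_median_equals_single_learner_score(self, small_cohort, small_features):
        fm = pc.binarize(small_cohort.expression, small_features)
        params = pc.ModelParams(ensemble_size=1, subsample_fraction=1.0, seed=4)
        model = pc.train(fm, small_cohort.labels, params)
        preds = pc.predict(model, small_cohort.expression)
        X = fm.values.astype(np.float32)
        for k, c in enumerate(model.label_set):
            single = model.stacks[c][0].predict_proba(X)[:, 1]
            assert np.allclose(preds.scores[:, k], single)

    def test_two_sample_cluster_trains(self):
        rng = np.random.default_rng(5)
        fm = pc.PairFeatureMatrix(
            [f"s{i}" for i in range(22)], ["c1:A<B", "c2:C<D"],
            rng.integers(0, 2, size=(22, 2)),
        )
        labels = pc.ClusterLabeling(
            {f"s{i}": ("c1" if i < 2 else "c2") for i in range(22)}, ["c1", "c2"]
        )
        model = pc.train(fm, labels, pc.ModelParams(seed=6))
        # every member of the tiny cluster's stack saw >= 1 positive example
        assert len(model.stacks["c1"]) == 11

    def test_single_cluster_sample_rejected(self):
        fm = pc.PairFeatureMatrix(
            ["s0", "s1", "s2"], ["c1:A<B"], np.array([[1], [0], [1]])
        )
        labels = pc.ClusterLabeling(
            {"s0": "c1", "s1": "c2", "s2": "c2"}, ["c1", "c2"]
        )
        with pytest.raises(ValidationError, match="c1"):
            pc.train(fm, labels, pc.ModelParams(seed=0))

    def test_single_sample_prediction(self, small_cohort, small_features):
        fm = pc.binarize(small_cohort.expression, small_features)
        model = pc.train(fm, small_cohort.labels, pc.ModelParams(seed=1))
        one = small_cohort.expression.select_samples(
            [small_cohort.expression.sample_ids[0]]
        )
        preds = pc.predict(model, one)
        assert len(preds.sample_ids) == 1 and len(preds.best_calls) == 1


class TestClassificationReport:
    def test_perfect_two_class(self):
        true = pc.ClusterLabeling(
            {f"s{i}": ("a" if i < 5 else "b") for i in range(10)}, ["a", "b"]
        )
        pred = pc.PredictionResult(
            [f"s{i}" for i in range(10)], ["a", "b"],
            np.tile([0.9, 0.1], (10, 1)),
            ["a"] * 5 + ["b"] * 5,
        )
        rep = pc.classification_report(true, pred)
        assert rep.accuracy == 1.0
        assert rep.per_cluster.loc["a", "f1"] == 1.0
        assert rep.macro_f1 == 1.0
        assert rep.confusion.values.sum() == 10

    def test_all_one_class_over_balanced_truth(self):
        true = pc.ClusterLabeling(
            {f"s{i}": ("a" if i < 5 else "b") for i in range(10)}, ["a", "b"]
        )
        pred = pc.PredictionResult(
            [f"s{i}" for i in range(10)], ["a", "b"],
            np.tile([0.9, 0.1], (10, 1)), ["a"] * 10,
        )
        rep = pc.classification_report(true, pred)
        assert rep.accuracy == 0.5
        assert rep.per_cluster.loc["a", "f1"] == pytest.approx(2 / 3)
        assert rep.per_cluster.loc["b", "f1"] == 0.0
        # every sample was called "a": no true negatives for a, none missed for b
        assert rep.per_cluster.loc["a", "specificity"] == 0.0
        assert rep.per_cluster.loc["b", "specificity"] == 1.0

    def test_disjoint_samples_error(self):
        true = pc.ClusterLabeling({"x": "a", "y": "b"}, ["a", "b"])
        pred = pc.PredictionResult(["z"], ["a", "b"], np.array([[0.5, 0.5]]), ["a"])
        with pytest.raises(ValidationError):
            pc.classification_report(true, pred)


class TestCrossValidate:
    def test_fold_count_guard(self, small_cohort, small_features):
        with pytest.raises(ValidationError, match="smallest cluster"):
            pc.cross_validate(
                small_cohort.expression, small_cohort.labels,
                pc.ModelParams(seed=0), feature_set=small_features, n_folds=11,
            )

    def test_exactly_one_feature_source(self, small_cohort, small_features):
        with pytest.raises(ValidationError):
            pc.cross_validate(
                small_cohort.expression, small_cohort.labels, pc.ModelParams(seed=0),
                feature_set=small_features, selection=pc.SelectionConfig(),
            )

    def test_in_fold_selection_on_separable_cohort(self, small_cohort):
        params = pc.ModelParams(ensemble_size=5, nrounds=20, max_depth=6, seed=3)
        res, rep = pc.cross_validate(
            small_cohort.expression, small_cohort.labels, params,
            selection=pc.SelectionConfig(k_per_cluster=3), n_folds=5,
        )
        assert set(res.sample_ids) == set(small_cohort.labels.assignments)
        assert rep.macro_f1 > 0.9


class TestImportance:
    def test_planted_pair_tops_gain(self):
        # one perfectly separating pair among 9 noise pairs
        rng = np.random.default_rng(8)
        n = 60
        y = np.array(["c1"] * 15 + ["c2"] * 45)
        cols = [(y == "c1").astype(np.int8)]
        ids = ["c1:SIG_A<SIG_B"]
        for i in range(9):
            cols.append(rng.integers(0, 2, n).astype(np.int8))
            ids.append(f"c1:N{i}_A<N{i}_B")
        fm = pc.PairFeatureMatrix(
            [f"s{i}" for i in range(n)], ids, np.column_stack(cols)
        )
        labels = pc.ClusterLabeling(
            {f"s{i}": y[i] for i in range(n)}, ["c1", "c2"]
        )
        model = pc.train(fm, labels, pc.ModelParams(seed=9))
        imp = pc.feature_importance(model)
        assert imp["c1"][0][0] == "c1:SIG_A<SIG_B"
        assert imp["c1"][0][1] > 0

    def test_deterministic_under_seed(self, small_cohort, small_features):
        fm = pc.binarize(small_cohort.expression, small_features)
        m1 = pc.train(fm, small_cohort.labels, pc.ModelParams(seed=10))
        m2 = pc.train(fm, small_cohort.labels, pc.ModelParams(seed=10))
        assert pc.feature_importance(m1) == pc.feature_importance(m2)

    def test_untrained_model_rejected(self, small_features):
        model = pc.EnsembleModel(small_features, pc.ModelParams(seed=0), ["a", "b"], [])
        with pytest.raises(ValidationError):
            pc.feature_importance(model)


class TestGridSearch:
    def test_single_point_grid(self, small_cohort, small_features):
        params, table = pc.grid_search(
            small_cohort.expression, small_cohort.labels, small_features,
            {"max_depth": [4]}, n_folds=3, seed=1,
            base_params=pc.ModelParams(ensemble_size=3, nrounds=10, seed=1),
        )
        assert params.max_depth == 4
        assert len(table) == 1

    def test_tie_break_prefers_smaller_depth(self, small_cohort, small_features):
        params, table = pc.grid_search(
            small_cohort.expression, small_cohort.labels, small_features,
            {"max_depth": [6, 3], "eta": [0.3, 0.1]}, n_folds=3, seed=2,
            base_params=pc.ModelParams(ensemble_size=3, nrounds=10, seed=2),
        )
        assert len(table) == 4
        best_f1 = table["macro_f1"].max()
        depths_at_best = table.loc[table["macro_f1"] == best_f1, "max_depth"]
        assert params.max_depth == depths_at_best.min()

    def test_unknown_parameter_rejected(self, small_cohort, small_features):
        with pytest.raises(ValidationError):
            pc.grid_search(
                small_cohort.expression, small_cohort.labels, small_features,
                {"bogus": [1]}, n_folds=3, seed=0,
            )
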