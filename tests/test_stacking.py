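import itertools

import numpy as np
import pytest

from tierstack.stacking import (
    CombinationScheme,
    FoldPlan,
    LearnerSpec,
    OOFPredictions,
    PassThroughClassifier,
    TieredStacking,
    TieredStackingResults,
    TraditionalStacking,
    build_meta_features,
    combine_average,
    combine_majority,
    default_learners,
    default_schemes,
    fit_base_tier,
    fit_tiered_ensemble,
    fit_traditional_se,
    make_learner,
    make_scheme,
    make_stratified_folds,
    register_learner,
)

from .oracles import majority_by_counting


class _Constant:
    """Test double: a learner that always scores 0.5."""

    def fit(self, X, y):
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        return np.full((len(X), 2), 0.5)


register_learner("const05", lambda **kw: _Constant())


def _toy(n=60, p=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(n, p)).astype(float)
    y = X[:, 0].astype(int)  # linearly coded, noise-free
    return X, y


class TestFolds:
    def test_balanced_classes_give_exact_per_fold_counts(self):
        y = np.array([0, 1] * 50)
        plan = make_stratified_folds(y, n_folds=10, seed=3)
        for f in range(10):
            te = plan.test_indices(f)
            assert len(te) == 10
            assert y[te].sum() == 5

    def test_n_equals_folds_gives_singletons(self):
        y = np.array([0] * 5 + [1] * 5)
        plan = make_stratified_folds(y, n_folds=10, seed=0)
        assert all(len(plan.test_indices(f)) == 1 for f in range(10))

    def test_same_seed_reproduces_plan(self):
        y = np.array([0] * 40 + [1] * 20)
        a = make_stratified_folds(y, 10, seed=9)
        b = make_stratified_folds(y, 10, seed=9)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_class_smaller_than_fold_count_still_balanced(self):
        y = np.array([0] * 50 + [1] * 5)
        plan = make_stratified_folds(y, 10, seed=0)
        pos = [y[plan.test_indices(f)].sum() for f in range(10)]
        assert max(pos) - min(pos) <= 1
        sizes = [len(plan.test_indices(f)) for f in range(10)]
        assert max(sizes) - min(sizes) <= 1

    def test_positive_counts_within_one_across_folds(self, rng):
        y = (rng.uniform(size=137) < 0.23).astype(int)
        if y.sum() < 10:
            y[:10] = 1
        plan = make_stratified_folds(y, 10, seed=5)
        pos = [y[plan.test_indices(f)].sum() for f in range(10)]
        assert max(pos) - min(pos) <= 1

    def test_folds_disjoint_and_exhaustive(self, rng):
        y = (rng.uniform(size=100) < 0.4).astype(int)
        plan = make_stratified_folds(y, 10, seed=1)
        seen = np.concatenate([plan.test_indices(f) for f in range(10)])
        assert sorted(seen.tolist()) == list(range(100))


class TestBaseTier:
    def test_every_cell_filled_once(self):
        X, y = _toy(n=50)
        folds = make_stratified_folds(y, 5, seed=0)
        learners = [LearnerSpec("logistic"), LearnerSpec("naive_bayes"), LearnerSpec("knn")]
        oof, fitted = fit_base_tier(X, y, learners, folds)
        assert oof.scores.shape == (50, 3)
        assert not np.isnan(oof.scores).any()
        assert len(fitted) == 3

    def test_constant_learner_yields_constant_column(self):
        X, y = _toy(n=40)
        folds = make_stratified_folds(y, 4, seed=0)
        oof, _ = fit_base_tier(
            X, y, [LearnerSpec("const05"), LearnerSpec("logistic")], folds
        )
        np.testing.assert_allclose(oof.scores[:, 0], 0.5)

    def test_decision_tree_perfect_on_linearly_coded_labels(self):
        X, y = _toy(n=80, seed=2)
        folds = make_stratified_folds(y, 5, seed=0)
        oof, _ = fit_base_tier(
            X, y, [LearnerSpec("decision_tree"), LearnerSpec("logistic")], folds
        )
        assert (oof.labels[:, 0] == y).mean() == 1.0

    def test_failing_learner_error_names_learner_and_fold(self):
        class _Broken:
            def fit(self, X, y):
                raise RuntimeError("boom")

        register_learner("broken", lambda **kw: _Broken())
        X, y = _toy(n=30)
        folds = make_stratified_folds(y, 3, seed=0)
        with pytest.raises(RuntimeError, match=r"'broken' failed to fit on fold 0"):
            fit_base_tier(X, y, [LearnerSpec("broken"), LearnerSpec("logistic")], folds)

    def test_oof_scores_range_validated(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            OOFPredictions(scores=np.array([[1.5]]), labels=np.array([[1]]))


class TestCombinationSchemes:
    def test_average_examples(self):
        assert combine_average([0.2, 0.4, 0.9]) == pytest.approx(0.5)
        assert combine_average([0.7]) == pytest.approx(0.7)

    def test_average_permutation_invariant(self, rng):
        v = rng.uniform(size=7)
        for _ in range(5):
            perm = rng.permutation(7)
            assert combine_average(v[perm]) == pytest.approx(combine_average(v))

    def test_average_empty_is_error(self):
        with pytest.raises(ValueError):
            combine_average([])

    def test_majority_strict_and_tie(self):
        assert combine_majority([1, 1, 0]) == 1
        assert combine_majority([0, 0, 1, 1]) == 1  # tie resolves to PTB
        assert combine_majority([0, 0, 0, 1]) == 0

    @pytest.mark.parametrize("m", [2, 3, 4, 5])
    def test_majority_matches_counting_oracle_on_all_patterns(self, m):
        for pattern in itertools.product([0, 1], repeat=m):
            assert combine_majority(list(pattern)) == majority_by_counting(pattern)

    def test_majority_empty_is_error(self):
        with pytest.raises(ValueError):
            combine_majority([])

    def test_product_rule_is_renormalized_geometric_mean(self):
        scheme = make_scheme("product")
        assert scheme.combine(np.array([0.25, 0.25])) == pytest.approx(0.25)
        assert scheme.combine(np.array([0.9, 0.4, 0.6])) == pytest.approx(
            (0.9 * 0.4 * 0.6) ** (1 / 3)
        )


class TestMetaFeatures:
    def _oof_single_row(self):
        scores = np.array([[0.9, 0.8, 0.2]])
        return OOFPredictions(scores=scores, labels=(scores >= 0.5).astype(int))

    def test_average_and_majority_row(self):
        oof = self._oof_single_row()
        meta = build_meta_features(oof, [make_scheme("average"), make_scheme("majority")])
        np.testing.assert_allclose(meta[0], [(0.9 + 0.8 + 0.2) / 3, 1.0])

    def test_column_count_equals_scheme_count(self, rng):
        scores = rng.uniform(size=(20, 4))
        oof = OOFPredictions(scores=scores, labels=(scores >= 0.5).astype(int))
        meta = build_meta_features(oof, default_schemes())
        assert meta.shape == (20, 4)

    def test_identical_learners_make_average_equal_single_column(self, rng):
        col = rng.uniform(size=15)
        scores = np.column_stack([col, col, col])
        oof = OOFPredictions(scores=scores, labels=(scores >= 0.5).astype(int))
        meta = build_meta_features(oof, [make_scheme("average")])
        np.testing.assert_allclose(meta[:, 0], col)

    def test_scheme_output_outside_unit_interval_rejected(self, rng):
        scores = rng.uniform(size=(5, 2))
        oof = OOFPredictions(scores=scores, labels=(scores >= 0.5).astype(int))
        bad = CombinationScheme("bad", "score", lambda s: 2.0)
        with pytest.raises(ValueError, match="outside"):
            build_meta_features(oof, [bad])

    def test_scheme_symmetry_under_learner_permutation(self, rng):
        scores = rng.uniform(size=(25, 5))
        perm = rng.permutation(5)
        for name in ("average", "majority", "max_score", "product"):
            a = build_meta_features(
                OOFPredictions(scores=scores, labels=(scores >= 0.5).astype(int)),
                [make_scheme(name)],
            )
            b = build_meta_features(
                OOFPredictions(
                    scores=scores[:, perm], labels=(scores[:, perm] >= 0.5).astype(int)
                ),
                [make_scheme(name)],
            )
            np.testing.assert_allclose(a, b)


class TestTieredModel:
    def test_level1_width_is_schemes_plus_three(self):
        X, y = _toy(n=100, p=6, seed=4)
        res = fit_tiered_ensemble(X, y, n_folds=5, seed=0)
        s = len(default_schemes())
        assert len(res.level1_columns) == s + 3
        assert len(res.selected_features) == 3

    def test_separable_data_held_out_accuracy_one(self):
        from tierstack.synthgen import generate_separable

        ds = generate_separable(200, seed=5)
        tr, te = np.arange(160), np.arange(160, 200)
        res = fit_tiered_ensemble(ds.X[tr], ds.y[tr], n_folds=5, seed=0)
        _, labels = res.predict(ds.X[te])
        assert (labels == ds.y[te]).mean() == 1.0

    def test_predict_scores_in_unit_interval_and_deterministic(self):
        X, y = _toy(n=90, p=5, seed=6)
        res = fit_tiered_ensemble(X, y, n_folds=5, seed=1)
        s1, l1 = res.predict(X)
        s2, _ = res.predict(X)
        assert (s1 >= 0).all() and (s1 <= 1).all()
        np.testing.assert_array_equal(s1, s2)
        # identical rows receive identical scores
        Xdup = np.vstack([X[0], X[0]])
        sd, _ = res.predict(Xdup)
        assert sd[0] == sd[1]

    def test_column_mismatch_rejected(self):
        X, y = _toy(n=60, p=4)
        res = fit_tiered_ensemble(X, y, n_folds=5, seed=0)
        with pytest.raises(ValueError, match="feature columns"):
            res.predict(np.zeros((3, 5)))

    def test_degenerate_config_reduces_to_soft_vote(self):
        X, y = _toy(n=80, p=4, seed=8)
        res = fit_tiered_ensemble(
            X, y,
            learners=[LearnerSpec("logistic"), LearnerSpec("naive_bayes"),
                      LearnerSpec("knn")],
            schemes=[make_scheme("average")],
            meta=LearnerSpec("passthrough"),
            k_meta=0,
            n_folds=5,
            seed=0,
        )
        scores, labels = res.predict(X)
        base = np.column_stack(
            [est.predict_proba(X)[:, 1] for est in res.base_learners]
        )
        np.testing.assert_allclose(scores, base.mean(axis=1), atol=1e-12)
        np.testing.assert_array_equal(labels, (base.mean(axis=1) >= 0.5).astype(int))

    def test_missing_values_rejected_at_construction(self):
        X, y = _toy(n=30)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            TieredStacking(X, y)

    def test_summary_mentions_tiers_and_roster(self):
        X, y = _toy(n=60, p=4)
        res = fit_tiered_ensemble(X, y, n_folds=5, seed=0)
        text = res.summary()
        assert "base learners" in text
        assert "meta-learner" in text
        assert "logistic" in text


class TestTraditionalSE:
    def test_level1_has_one_column_per_learner(self):
        X, y = _toy(n=70, p=4, seed=3)
        learners = default_learners()
        res = fit_traditional_se(X, y, learners=learners, n_folds=5, seed=0)
        assert len(res.level1_columns) == len(learners)
        assert res.variant == "traditional"

    def test_shares_fold_plan_with_proposed_under_same_seed(self):
        X, y = _toy(n=80, p=4, seed=9)
        a = fit_tiered_ensemble(X, y, n_folds=5, seed=12)
        b = fit_traditional_se(X, y, n_folds=5, seed=12)
        np.testing.assert_array_equal(a.fold_plan.assignments, b.fold_plan.assignments)

    def test_separable_data_held_out_accuracy_one(self):
        from tierstack.synthgen import generate_separable

        ds = generate_separable(200, seed=11)
        tr, te = np.arange(160), np.arange(160, 200)
        res = fit_traditional_se(ds.X[tr], ds.y[tr], n_folds=5, seed=0)
        _, labels = res.predict(ds.X[te])
        assert (labels == ds.y[te]).mean() == 1.0


class TestSerialization:
    def test_save_load_roundtrip_preserves_predictions(self, tmp_path):
        X, y = _toy(n=60, p=4, seed=13)
        res = fit_tiered_ensemble(X, y, n_folds=5, seed=0)
        path = tmp_path / "model.joblib"
        res.save(path)
        loaded, prep = TieredStackingResults.load(path)
        assert prep is None
        np.testing.assert_array_equal(loaded.predict(X)[0], res.predict(X)[0])
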