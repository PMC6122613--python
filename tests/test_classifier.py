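"""PLS-LDA building blocks, the balanced repeated CV engine, ablation,
stage-wise LOOCV and the SUVmax augmentation."""

import numpy as np
import pandas as pd
import pytest

from lungdx.classifier import (
    ClassifierError,
    CVConfig,
    ablation_cv,
    augment_with_suvmax,
    balanced_repeated_cv,
    fit_pls,
    fit_pls_lda,
    lasso_top_k,
    loocv_per_stage,
    predict,
)
from tests.conftest import small_config
from lungdx.ir_features import normalize_cohort
from lungdx.synthetic_cohort import generate_cohort


def two_clouds(rng, n=20, sep=5.0, p=2):
    X = np.vstack([rng.normal(0, 1, (n, p)), rng.normal(0, 1, (n, p))])
    X[:n, 0] -= sep / 2
    X[n:, 0] += sep / 2
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestLassoTopK:
    def test_orthonormal_design_entry_order_is_correlation_order(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(60, 10)))
        y = np.where(rng.random(60) > 0.5, "a", "b")
        yy = np.where(y == "b", 1.0, -1.0)
        oracle = np.argsort(-np.abs(Q.T @ yy))
        np.testing.assert_array_equal(lasso_top_k(Q, y, 10), oracle)

    def test_k_zero_returns_empty_selection(self, rng):
        X, y = two_clouds(rng)
        assert lasso_top_k(X, y, 0).size == 0

    def test_duplicate_columns_resolved_to_smaller_index(self, rng):
        X, y = two_clouds(rng, p=4)
        X_dup = np.column_stack([X, X[:, 0]])  # column 4 duplicates column 0
        selected = lasso_top_k(X_dup, y, 5)
        assert 0 in selected
        assert 4 not in selected

    def test_invalid_inputs_rejected(self, rng):
        X, y = two_clouds(rng)
        with pytest.raises(ClassifierError):
            lasso_top_k(X, y, X.shape[1] + 1)
        with pytest.raises(ClassifierError):
            lasso_top_k(X, np.array(["a"] * len(y)), 1)


class TestFitPLS:
    def test_single_feature_component_is_the_feature_up_to_sign(self, rng):
        x = rng.normal(0, 1, 30)
        x = (x - x.mean()) / x.std(ddof=1)
        y = rng.choice([-1.0, 1.0], 30)
        est = fit_pls(x[:, None], y, 1)
        scores = est.transform(x[:, None]).ravel()
        ratio = scores / (x - x.mean())
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-8)

    def test_full_rank_pls_equals_least_squares(self, rng):
        n, p = 25, 4
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        est = fit_pls(X, y, p)
        Xc = np.column_stack([np.ones(n), X])
        beta = np.linalg.lstsq(Xc, y, rcond=None)[0]
        np.testing.assert_allclose(est.predict(X).ravel(), Xc @ beta, rtol=1e-6)

    def test_score_vectors_are_orthogonal(self, rng):
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        est = fit_pls(X, y, 5)
        T = est.transform(X)
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_component_count_bounds_enforced(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        with pytest.raises(ClassifierError):
            fit_pls(X, y, 0)
        with pytest.raises(ClassifierError):
            fit_pls(X, y, 4)


class TestFitPLSLDA:
    def test_separable_clouds_fit_without_training_errors(self, rng):
        X, y = two_clouds(rng)
        model = fit_pls_lda(X, y, top_k=2, n_components=1)
        pred, _ = predict(model, X)
        assert np.all(pred == y)

    def test_full_rank_matches_direct_lda_on_scaled_features(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, y = two_clouds(rng, n=25, sep=2.0, p=3)
        model = fit_pls_lda(X, y, top_k=3, n_components=3)
        pred, _ = predict(model, X)
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        direct = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(Xs, y)
        assert np.mean(pred == direct.predict(Xs)) == 1.0

    def test_boundary_point_assigned_to_first_sorted_class(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array(["a", "a", "b", "b"])
        model = fit_pls_lda(X, y, top_k=1, n_components=1)
        pred, d = predict(model, np.array([[0.0]]))
        assert d[0] == pytest.approx(0.0, abs=1e-12)
        assert pred[0] == "a"

    def test_predictions_deterministic_and_rowwise(self, rng):
        X, y = two_clouds(rng)
        model = fit_pls_lda(X, y, top_k=2, n_components=1)
        X_new = rng.normal(size=(5, 2))
        p1, _ = predict(model, X_new)
        p2, _ = predict(model, np.vstack([X_new, X_new]))
        np.testing.assert_array_equal(np.concatenate([p1, p1]), p2)

    def test_dimension_mismatch_rejected(self, rng):
        X, y = two_clouds(rng)
        model = fit_pls_lda(X, y, top_k=2, n_components=1)
        with pytest.raises(ClassifierError, match="features"):
            predict(model, np.zeros((3, 5)))


def _pair(cohort):
    X = cohort.feature_matrix()
    y = cohort.labels()
    mask = y.isin(["cancer", "inflammation"])
    return X[mask], y[mask]


class TestBalancedRepeatedCV:
    def test_evaluation_count_and_balance(self, one_signal_cohort_normalized):
        X, y = _pair(one_signal_cohort_normalized)
        cfg = CVConfig(n_repeats=5, n_folds=4, top_k=8, seed=0)
        res = balanced_repeated_cv(X, y, cfg, "cancer")
        assert res.n_evaluations == 20
        for counts in res.balanced_class_counts:
            assert counts == {"cancer": 40, "inflammation": 40}

    def test_same_master_seed_reproduces_result(self, one_signal_cohort_normalized):
        X, y = _pair(one_signal_cohort_normalized)
        cfg = CVConfig(n_repeats=3, n_folds=4, top_k=8, seed=9)
        a = balanced_repeated_cv(X, y, cfg, "cancer")
        b = balanced_repeated_cv(X, y, cfg, "cancer")
        assert a.per_eval.equals(b.per_eval)
        assert a.selection_frequency == b.selection_frequency

    def test_glutamate_always_selected_on_one_signal_cohort(self, one_signal_cohort_normalized):
        X, y = _pair(one_signal_cohort_normalized)
        cfg = CVConfig(n_repeats=5, n_folds=4, top_k=16, seed=1)
        res = balanced_repeated_cv(X, y, cfg, "cancer")
        assert res.selection_frequency["IR89"] == 1.0

    def test_mce_complements_mean_of_sensitivity_and_specificity(self, one_signal_cohort_normalized):
        X, y = _pair(one_signal_cohort_normalized)
        cfg = CVConfig(n_repeats=4, n_folds=4, top_k=8, seed=2)
        res = balanced_repeated_cv(X, y, cfg, "cancer")
        for _, row in res.per_eval.iterrows():
            # folds of a 40+40 balanced set hold 20 subjects, 10 per class
            assert row["mce"] == pytest.approx(
                1 - (row["sensitivity"] + row["specificity"]) / 2, abs=1 / row["n_test"]
            )

    def test_permuted_labels_give_chance_level_error(self, one_signal_cohort_normalized):
        X, y = _pair(one_signal_cohort_normalized)
        rng = np.random.default_rng(5)
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        cfg = CVConfig(n_repeats=20, n_folds=4, top_k=8, seed=3)
        res = balanced_repeated_cv(X, y_perm, cfg, "cancer")
        per_repeat = res.per_eval.groupby("repeat")["mce"].mean()
        se = per_repeat.std(ddof=1) / np.sqrt(len(per_repeat))
        assert abs(res.mce_mean - 0.5) < 3 * se + 1e-9

    def test_minority_class_smaller_than_folds_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        y = np.array(["a"] * 7 + ["b"] * 3)
        with pytest.raises(ClassifierError, match="fewer than n_folds"):
            balanced_repeated_cv(X, y, CVConfig(n_repeats=1, n_folds=4, top_k=2, seed=0))


class TestAblation:
    def test_empty_removal_is_identical_to_plain_cv(self, one_signal_cohort_normalized):
        X, y = _pair(one_signal_cohort_normalized)
        cfg = CVConfig(n_repeats=3, n_folds=4, top_k=8, seed=4)
        base = balanced_repeated_cv(X, y, cfg, "cancer")
        noop = ablation_cv(X, y, cfg, [], "cancer")
        assert base.per_eval.equals(noop.per_eval)

    def test_removing_the_signal_region_increases_error(self, one_signal_cohort_normalized):
        X, y = _pair(one_signal_cohort_normalized)
        cfg = CVConfig(n_repeats=20, n_folds=4, top_k=16, seed=6)
        base = balanced_repeated_cv(X, y, cfg, "cancer")
        ablated = ablation_cv(X, y, cfg, ["IR89"], "cancer")
        assert ablated.mce_mean > base.mce_mean

    def test_removing_a_background_region_changes_little(self, one_signal_cohort_normalized):
        X, y = _pair(one_signal_cohort_normalized)
        cfg = CVConfig(n_repeats=10, n_folds=4, top_k=8, seed=7)
        base = balanced_repeated_cv(X, y, cfg, "cancer")
        ablated = ablation_cv(X, y, cfg, ["IR30"], "cancer")
        assert abs(ablated.mce_mean - base.mce_mean) < 0.05

    def test_removing_everything_rejected(self, one_signal_cohort_normalized):
        X, y = _pair(one_signal_cohort_normalized)
        cfg = CVConfig(n_repeats=1, n_folds=4, top_k=2, seed=0)
        with pytest.raises(ClassifierError, match="every feature"):
            ablation_cv(X, y, cfg, list(X.columns), "cancer")


class TestLoocvPerStage:
    def test_separable_toy_has_zero_error_everywhere(self, rng):
        n = 12
        X = pd.DataFrame(np.vstack([rng.normal(-8, 0.5, (n, 2)), rng.normal(8, 0.5, (n, 2))]))
        y = np.array(["cancer"] * n + ["inflammation"] * n)
        stages = ["IA"] * 6 + ["IV"] * 6 + [None] * n
        res = loocv_per_stage(X, y, stages, top_k=2, n_components=1, seed=0,
                              pos_label="cancer")
        assert res.overall_mce == 0.0
        assert (res.per_stage["mce"] == 0.0).all()
        assert res.n_evaluations == 2 * n

    def test_shuffled_stages_have_homogeneous_error(self):
        cohort = normalize_cohort(generate_cohort(small_config(seed=8, effects=())))
        X = cohort.feature_matrix()
        y = cohort.labels()
        mask = y.isin(["cancer", "inflammation"])
        rng = np.random.default_rng(0)
        stages = np.array([s.stage for s in cohort.subjects], dtype=object)[mask.to_numpy()]
        cancer = np.flatnonzero(y[mask].to_numpy() == "cancer")
        stages[cancer] = rng.permutation(stages[cancer])
        res = loocv_per_stage(X[mask], y[mask].to_numpy(), stages, top_k=8,
                              n_components=2, seed=1, pos_label="cancer")
        overall = res.per_stage["errors"].sum() / res.per_stage["n"].sum()
        for _, row in res.per_stage.iterrows():
            if row["n"] == 0:
                continue
            tol = 3 * np.sqrt(max(overall * (1 - overall), 0.01) / row["n"])
            assert abs(row["mce"] - overall) <= tol

    def test_empty_stage_reported_as_undefined(self, rng):
        n = 10
        X = pd.DataFrame(np.vstack([rng.normal(-8, 0.5, (n, 2)), rng.normal(8, 0.5, (n, 2))]))
        y = np.array(["cancer"] * n + ["inflammation"] * n)
        stages = ["IA"] * n + [None] * n
        res = loocv_per_stage(X, y, stages, top_k=2, n_components=1, seed=0,
                              stage_order=["IA", "IV"])
        row = res.per_stage.set_index("stage").loc["IV"]
        assert row["n"] == 0 and np.isnan(row["mce"])


class TestAugmentWithSuvmax:
    def test_appends_exactly_one_column(self, small_cohort_normalized):
        X, y = _pair(small_cohort_normalized)
        suv = pd.Series([s.suvmax for s in small_cohort_normalized.subjects],
                        index=[s.id for s in small_cohort_normalized.subjects])
        out = augment_with_suvmax(X, suv.loc[X.index])
        assert out.shape[1] == X.shape[1] + 1
        assert list(out.columns)[-1] == "SUVmax"

    def test_missing_values_rejected_with_subject_ids(self, small_cohort_normalized):
        X, y = _pair(small_cohort_normalized)
        suv = pd.Series(np.nan, index=X.index)
        suv.iloc[1:] = 5.0
        with pytest.raises(ClassifierError, match=X.index[0]):
            augment_with_suvmax(X, suv)

    def test_constant_suvmax_rejected_at_scaling(self, small_cohort_normalized):
        X, y = _pair(small_cohort_normalized)
        suv = pd.Series(2.5, index=X.index)
        out = augment_with_suvmax(X, suv)
        with pytest.raises(ClassifierError, match="zero-variance"):
            fit_pls_lda(out.to_numpy(), y.to_numpy(), top_k=4, n_components=1)

    def test_informative_suvmax_is_frequently_selected(self, small_cohort_normalized):
        X, y = _pair(small_cohort_normalized)
        suv = pd.Series([s.suvmax for s in small_cohort_normalized.subjects],
                        index=[s.id for s in small_cohort_normalized.subjects])
        out = augment_with_suvmax(X, suv.loc[X.index])
        cfg = CVConfig(n_repeats=5, n_folds=4, top_k=16, seed=10)
        res = balanced_repeated_cv(out, y, cfg, "cancer")
        assert res.selection_frequency["SUVmax"] > 0.5
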