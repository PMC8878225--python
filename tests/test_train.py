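import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from perturbrank.train import (TrainedModelBundle, build_cv_plan, evaluate_scores,
                               fit_ensemble, make_class_weights, make_estimator,
                               nested_cv_train, _fit, _proba)

from conftest import TINY_GRIDS
from oracles import average_precision_enum, roc_auc_pairs


# ---------------------------------------------------------------------------
# class weights
# ---------------------------------------------------------------------------

def test_minority_weight_is_majority_over_minority():
    y = pd.Series([1] * 10 + [0] * 90)
    assert make_class_weights(y) == {1: 9.0, 0: 1.0}


def test_balanced_classes_get_unit_weights():
    assert make_class_weights(np.array([0, 1] * 25)) == {0: 1.0, 1: 1.0}


def test_single_class_labels_rejected():
    with pytest.raises(ValueError, match="both classes"):
        make_class_weights(np.zeros(10))


# ---------------------------------------------------------------------------
# CV plan
# ---------------------------------------------------------------------------

def test_plan_tiny_dataset_equal_folds():
    y = np.array([0, 1] * 5)
    plan = build_cv_plan(10, seed=0, labels=y)
    assert all(len(f.test) == 2 for f in plan.folds)


def test_plan_deterministic_per_seed():
    y = np.array([0] * 40 + [1] * 10)
    p1 = build_cv_plan(50, seed=3, labels=y)
    p2 = build_cv_plan(50, seed=3, labels=y)
    for f1, f2 in zip(p1.folds, p2.folds):
        np.testing.assert_array_equal(f1.test, f2.test)
        np.testing.assert_array_equal(f1.tune, f2.tune)
        np.testing.assert_array_equal(f1.train, f2.train)


def test_plan_too_few_positives_suggests_override():
    y = np.array([1] * 3 + [0] * 47)
    with pytest.raises(ValueError, match="stratified=False"):
        build_cv_plan(50, seed=0, labels=y)
    plan = build_cv_plan(50, seed=0, labels=y, stratified=False)
    plan.check_partition(50)


@settings(deadline=None, max_examples=20)
@given(n=st.integers(20, 120), seed=st.integers(0, 1000))
def test_plan_partitions_rows_exactly_once(n, seed):
    rng = np.random.default_rng(seed)
    y = np.zeros(n, int)
    y[rng.choice(n, size=max(5, n // 4), replace=False)] = 1
    plan = build_cv_plan(n, seed=seed, labels=y)
    plan.check_partition(n)  # raises on any violation
    sizes = [len(f.test) for f in plan.folds]
    assert max(sizes) - min(sizes) <= 1
    for f in plan.folds:
        expect = int(np.rint((n - len(f.test)) / 5))
        assert len(f.tune) == expect


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

def test_perfect_separation_and_all_ties():
    y = np.array([1, 1, 0, 0])
    roc, _ = evaluate_scores(np.array([0.9, 0.8, 0.2, 0.1]), y)
    assert roc == 1.0
    roc_tied, _ = evaluate_scores(np.full(4, 0.5), y)
    assert roc_tied == 0.5


def test_metrics_match_bruteforce_on_mixed_example():
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    y = np.array([1, 0, 1, 0])
    roc, ap = evaluate_scores(scores, y)
    assert roc == pytest.approx(roc_auc_pairs(scores, y), abs=1e-12)
    assert ap == pytest.approx(average_precision_enum(scores, y), abs=1e-12)
    # frozen values from the pair-counting / enumeration oracles
    assert roc == pytest.approx(0.75, abs=1e-12)
    assert ap == pytest.approx(0.5 + 1.0 / 3.0, abs=1e-12)


def test_metrics_match_bruteforce_with_ties():
    scores = np.array([0.5, 0.5, 0.5, 0.9, 0.1, 0.9])
    y = np.array([1, 0, 1, 1, 0, 0])
    roc, ap = evaluate_scores(scores, y)
    assert roc == pytest.approx(roc_auc_pairs(scores, y), abs=1e-12)
    assert ap == pytest.approx(average_precision_enum(scores, y), abs=1e-12)


def test_single_class_evaluation_rejected():
    with pytest.raises(ValueError):
        evaluate_scores(np.array([0.1, 0.2]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# nested CV
# ---------------------------------------------------------------------------

def test_single_grid_point_selected_everywhere(small_bundle):
    bundle, report = nested_cv_train(small_bundle.drug_matrix, small_bundle.labels,
                                     "en", grid=TINY_GRIDS["en"], seed=11)
    assert all(p == TINY_GRIDS["en"][0] for p in bundle.fold_params)
    assert bundle.final_params == TINY_GRIDS["en"][0]
    assert bundle.oof.between(0, 1).all() and not bundle.oof.isna().any()


def test_oof_probabilities_are_leak_free(small_bundle):
    """Every drug's out-of-fold probability comes from a model whose fitting
    and tuning indices exclude that drug."""
    plan = build_cv_plan(len(small_bundle.labels), 11, small_bundle.labels)
    covered = np.zeros(len(small_bundle.labels), dtype=int)
    for fold in plan.folds:
        covered[fold.test] += 1
        assert np.intersect1d(fold.test, np.concatenate([fold.tune, fold.train])).size == 0
    np.testing.assert_array_equal(covered, 1)


def test_empty_grid_rejected(small_bundle):
    with pytest.raises(ValueError, match="grid"):
        nested_cv_train(small_bundle.drug_matrix, small_bundle.labels, "en", grid=[])


def test_grid_selection_prefers_better_tuning_auc(small_bundle):
    # a grid mixing an absurdly strong penalty with a reasonable one must
    # not pick the strong penalty in every fold on separable data
    grid = [{"C": 1e-6, "l1_ratio": 0.5}, {"C": 1.0, "l1_ratio": 0.5}]
    bundle, _ = nested_cv_train(small_bundle.drug_matrix, small_bundle.labels,
                                "en", grid=grid, seed=11)
    assert any(p == grid[1] for p in bundle.fold_params)


def test_permuted_labels_give_chance_level_auc(small_bundle):
    """Permutation null: mean held-out ROC-AUC over 50 label shuffles ~ 0.5."""
    rng = np.random.default_rng(0)
    means = []
    y = small_bundle.labels
    for _ in range(50):
        perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        _, report = nested_cv_train(small_bundle.drug_matrix, perm, "en",
                                    grid=TINY_GRIDS["en"], seed=int(rng.integers(2**31)))
        means.append(report[report["fold"] == "mean"]["roc_auc"].iloc[0])
    assert abs(np.mean(means) - 0.5) < 0.1


def test_stronger_minority_weight_raises_minority_probabilities(small_bundle):
    X = small_bundle.drug_matrix.data.to_numpy()
    y = small_bundle.labels.to_numpy()
    minority = y == 1
    est_flat = make_estimator("en", {"C": 1.0, "l1_ratio": 0.5}, seed=0)
    est_flat.fit(X, y)  # unit weights
    est_weighted = _fit(make_estimator("en", {"C": 1.0, "l1_ratio": 0.5}, seed=0), X, y)
    assert _proba(est_weighted, X)[minority].mean() > _proba(est_flat, X)[minority].mean()


def test_scaling_option_runs_inside_pipeline(small_bundle):
    bundle, report = nested_cv_train(small_bundle.drug_matrix, small_bundle.labels,
                                     "en", grid=TINY_GRIDS["en"], seed=11, scale=True)
    assert bundle.oof.between(0, 1).all()
    assert report[report["fold"] == "mean"]["roc_auc"].iloc[0] > 0.8


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

def _fake_bundle(method, oof):
    return TrainedModelBundle(method=method, feature_names=pd.Index([]),
                              model=None, final_params={}, fold_params=[],
                              oof=oof)


def test_ensemble_of_perfect_predictors_reproduces_labels(small_bundle):
    y = small_bundle.labels
    perfect = y.astype(float)
    bundles = {m: _fake_bundle(m, perfect.copy()) for m in ("svm", "rf", "gbm", "en")}
    ens = fit_ensemble(bundles, y)
    probs = ens.predict(pd.DataFrame({m: perfect for m in bundles}))
    roc, _ = evaluate_scores(probs, y)
    assert roc == 1.0


def test_ensemble_tracks_single_informative_predictor(small_bundle, small_trained):
    trained, _, _ = small_trained
    y = small_bundle.labels
    informative = trained["en"].oof
    bundles = {"en": trained["en"]}
    for m in ("svm", "rf", "gbm"):
        bundles[m] = _fake_bundle(m, pd.Series(0.5, index=y.index))
    ens = fit_ensemble(bundles, y)
    probs = ens.predict(pd.DataFrame({m: bundles[m].oof for m in bundles}))
    auc_ens, _ = evaluate_scores(probs, y)
    auc_inf, _ = evaluate_scores(informative, y)
    assert auc_ens >= auc_inf - 0.05


def test_ensemble_mismatched_drug_sets_rejected(small_bundle):
    y = small_bundle.labels
    a = _fake_bundle("en", pd.Series(0.5, index=y.index))
    b = _fake_bundle("rf", pd.Series(0.5, index=y.index[:-1]))
    with pytest.raises(ValueError, match="drug sets"):
        fit_ensemble({"en": a, "rf": b}, y)
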