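"""Class-weighted classifiers under nested 5-fold cross-validation.

Four classifier families are supported — RBF support vector machine
(``svm``), random forest (``rf``), gradient boosting (``gbm``) and
elastic-net logistic regression (``en``) — plus a logistic "ensemble"
integrator fitted on the base models' out-of-fold probabilities.

The nested scheme: the drugs are split into 5 stratified outer folds.
Within each outer run, the non-held-out rows are further split into a
tuning subset (one fifth, nearest integer) and a training subset. Every
hyperparameter grid point is fitted on the training subset and scored on
the tuning subset by ROC-AUC; the winner is refitted on training + tuning
and evaluated once on the held-out fold, which never participates in
selection. The final scoring model is refitted on all drugs with the
modal selected hyperparameters.

Class imbalance is handled by weighting: every fit receives per-sample
weights with minority-class weight N_majority / N_minority and majority
weight 1. SVM probabilities are calibrated by Platt scaling
(``SVC(probability=True)``); the other families expose probabilities
natively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

METHODS = ("svm", "rf", "gbm", "en")

__all__ = ["METHODS", "CVFold", "CVPlan", "TrainedModelBundle", "EnsembleModel",
           "make_class_weights", "build_cv_plan", "default_grids", "make_estimator",
           "nested_cv_train", "evaluate_scores", "fit_ensemble"]


def make_class_weights(labels: pd.Series | np.ndarray) -> dict[int, float]:
    """Balanced weights: minority class gets N_majority / N_minority, majority 1."""
    y = np.asarray(labels)
    counts = {0: int((y == 0).sum()), 1: int((y == 1).sum())}
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("both classes must be present to derive class weights")
    minority = 0 if counts[0] < counts[1] else 1
    if counts[0] == counts[1]:
        return {0: 1.0, 1: 1.0}
    return {minority: counts[1 - minority] / counts[minority], 1 - minority: 1.0}


def _sample_weights(y: np.ndarray) -> np.ndarray:
    cw = make_class_weights(y)
    return np.array([cw[int(v)] for v in y])


@dataclass
class CVFold:
    test: np.ndarray    # held-out rows, used only for evaluation
    tune: np.ndarray    # hyperparameter-selection rows
    train: np.ndarray   # fitting rows


@dataclass
class CVPlan:
    folds: list[CVFold]
    seed: int
    stratified: bool

    def check_partition(self, n_rows: int) -> None:
        seen = np.concatenate([f.test for f in self.folds])
        if not np.array_equal(np.sort(seen), np.arange(n_rows)):
            raise AssertionError("outer folds do not partition the rows")
        for f in self.folds:
            if np.intersect1d(f.tune, f.train).size:
                raise AssertionError("tuning and training subsets overlap")
            rest = np.sort(np.concatenate([f.tune, f.train]))
            expect = np.sort(np.setdiff1d(np.arange(n_rows), f.test))
            if not np.array_equal(rest, expect):
                raise AssertionError("tune + train do not cover the non-held-out rows")


def build_cv_plan(n_rows: int, seed: int, labels: pd.Series | np.ndarray,
                  n_folds: int = 5, stratified: bool = True) -> CVPlan:
    """Nested CV plan: 5 outer folds; inner tuning subset = 1/5 of the rest.

    Outer folds are stratified by label (override with ``stratified=False``
    when there are too few positives). Fold sizes differ by at most one;
    the tuning subset size is the nearest integer to one fifth of the
    non-held-out rows.
    """
    y = np.asarray(labels)
    if n_rows < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} rows for {n_folds}-fold nesting")
    if len(y) != n_rows:
        raise ValueError("labels must align with rows")
    if stratified and min((y == 0).sum(), (y == 1).sum()) < n_folds:
        raise ValueError(
            "too few members of one class to stratify into "
            f"{n_folds} folds; pass stratified=False to override")
    splitter = (StratifiedKFold(n_folds, shuffle=True, random_state=seed)
                if stratified else KFold(n_folds, shuffle=True, random_state=seed))
    folds = []
    inner_seeds = np.random.SeedSequence(seed).generate_state(n_folds) % (2 ** 31)
    for k, (rest, test) in enumerate(splitter.split(np.zeros(n_rows), y)):
        n_tune = int(np.rint(len(rest) / n_folds))
        train_idx, tune_idx = train_test_split(
            rest, test_size=n_tune, random_state=int(inner_seeds[k]),
            stratify=y[rest] if stratified else None)
        folds.append(CVFold(test=np.sort(test), tune=np.sort(tune_idx),
                            train=np.sort(train_idx)))
    plan = CVPlan(folds=folds, seed=seed, stratified=stratified)
    plan.check_partition(n_rows)
    return plan


def default_grids() -> dict[str, list[dict]]:
    """Per-method hyperparameter grids (order matters: ties go to the first)."""
    en = [{"l1_ratio": r, "C": c}
          for r in (0.1, 0.5, 0.9)
          for c in np.logspace(-2, 2, 5)]
    svm = [{"C": c, "gamma": g} for c in (0.1, 1.0, 10.0) for g in ("scale", 0.01)]
    rf = [{"n_estimators": 500, "max_features": mf} for mf in ("sqrt", 0.1)]
    gbm = [{"n_estimators": n, "max_depth": d, "learning_rate": 0.1}
           for n in (100, 300) for d in (2, 3)]
    return {"en": en, "svm": svm, "rf": rf, "gbm": gbm}


def make_estimator(method: str, params: Mapping, seed: int = 0, scale: bool = False):
    """Instantiate one classifier; optionally prepend a standard scaler."""
    if method == "svm":
        # Platt-scaled probabilities via an internal calibration split
        est = CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=seed, **params), ensemble=False)
    elif method == "rf":
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    elif method == "gbm":
        est = GradientBoostingClassifier(random_state=seed, **params)
    elif method == "en":
        kwargs = {"max_iter": 5000, "tol": 1e-4, **params}
        est = LogisticRegression(solver="saga", random_state=seed, **kwargs)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if scale:
        est = Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def _fit(est, X: np.ndarray, y: np.ndarray):
    sw = _sample_weights(y)
    if isinstance(est, Pipeline):
        est.fit(X, y, clf__sample_weight=sw)
    else:
        est.fit(X, y, sample_weight=sw)
    return est


def _proba(est, X: np.ndarray) -> np.ndarray:
    return est.predict_proba(X)[:, list(est.classes_).index(1)]


def evaluate_scores(scores: np.ndarray | pd.Series,
                    labels: np.ndarray | pd.Series) -> tuple[float, float]:
    """(ROC-AUC, PR-AUC) for continuous scores against binary labels.

    ROC-AUC follows the rank / Mann-Whitney formulation with ties counting
    one half; PR-AUC is average precision (step-wise integral, no
    trapezoidal interpolation).
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to evaluate")
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


@dataclass
class TrainedModelBundle:
    """One fitted classifier family plus its cross-validation byproducts."""

    method: str
    feature_names: pd.Index
    model: object                       # final refit on all rows
    final_params: dict
    fold_params: list[dict]             # winner per outer fold
    oof: pd.Series                      # out-of-fold probability per drug
    scale: bool = False

    def predict_matrix(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != list(self.feature_names):
            raise ValueError(
                "column mismatch with the training gene space; "
                "run harmonize_genes first")
        return _proba(self.model, X.to_numpy())


def nested_cv_train(matrix, labels: pd.Series, method: str,
                    grid: Sequence[Mapping] | None = None,
                    plan: CVPlan | None = None, seed: int = 0,
                    scale: bool = False) -> tuple[TrainedModelBundle, pd.DataFrame]:
    """Run nested CV for one method; return the fitted bundle and a report.

    ``matrix`` may be an :class:`~perturbrank.io.ExpressionMatrix` or a
    DataFrame aligned with ``labels``. The report has one row per outer
    fold (selected hyperparameters, held-out ROC-AUC and PR-AUC) plus a
    ``mean`` row over the folds whose held-out metrics were defined.
    """
    X_df = matrix.data if hasattr(matrix, "data") else matrix
    if not X_df.index.equals(labels.index):
        labels = labels.reindex(X_df.index)
        if labels.isna().any():
            raise ValueError("labels missing for some matrix rows")
    X = X_df.to_numpy()
    y = labels.to_numpy().astype(int)
    if grid is None:
        grid = default_grids()[method]
    grid = [dict(g) for g in grid]
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    if plan is None:
        plan = build_cv_plan(len(y), seed, y)

    oof = pd.Series(np.nan, index=X_df.index, name=method)
    fold_rows, fold_params = [], []
    for k, fold in enumerate(plan.folds):
        tune_scores = []
        for params in grid:
            est = _fit(make_estimator(method, params, seed=seed, scale=scale),
                       X[fold.train], y[fold.train])
            p_tune = _proba(est, X[fold.tune])
            if len(np.unique(y[fold.tune])) < 2:
                tune_scores.append(0.5)
            else:
                tune_scores.append(roc_auc_score(y[fold.tune], p_tune))
        best = int(np.argmax(tune_scores))  # argmax takes the first on ties
        winner = grid[best]
        fold_params.append(winner)
        fit_idx = np.concatenate([fold.train, fold.tune])
        est = _fit(make_estimator(method, winner, seed=seed, scale=scale),
                   X[fit_idx], y[fit_idx])
        p_test = _proba(est, X[fold.test])
        oof.iloc[fold.test] = p_test
        if len(np.unique(y[fold.test])) < 2:
            logger.warning("fold %d held-out set has a single class; metrics undefined", k)
            roc = pr = np.nan
        else:
            roc, pr = evaluate_scores(p_test, y[fold.test])
        fold_rows.append({"fold": k, "params": repr(winner),
                          "tune_auc": float(tune_scores[best]),
                          "roc_auc": roc, "pr_auc": pr})
        logger.info("method=%s fold=%d selected %s (tune AUC %.3f)",
                    method, k, winner, tune_scores[best])

    # modal hyperparameters across folds; ties resolved by grid order
    keys = [repr(p) for p in fold_params]
    counts = pd.Series(keys).value_counts()
    top = counts[counts == counts.max()].index
    final_params = next(dict(g) for g in grid if repr(g) in set(top))
    final = _fit(make_estimator(method, final_params, seed=seed, scale=scale), X, y)

    report = pd.DataFrame(fold_rows)
    mean_row = {"fold": "mean", "params": repr(final_params),
                "tune_auc": report["tune_auc"].mean(),
                "roc_auc": report["roc_auc"].mean(skipna=True),
                "pr_auc": report["pr_auc"].mean(skipna=True)}
    report = pd.concat([report, pd.DataFrame([mean_row])], ignore_index=True)

    bundle = TrainedModelBundle(method=method, feature_names=X_df.columns,
                                model=final, final_params=final_params,
                                fold_params=fold_params, oof=oof, scale=scale)
    return bundle, report


@dataclass
class EnsembleModel:
    """Weighted logistic integrator over the base methods' probabilities."""

    methods: tuple[str, ...]
    model: LogisticRegression

    def predict(self, probs: pd.DataFrame) -> np.ndarray:
        X = probs.loc[:, list(self.methods)].to_numpy()
        return self.model.predict_proba(X)[:, list(self.model.classes_).index(1)]

    @property
    def intercept(self) -> float:
        return float(self.model.intercept_[0])

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.model.coef_[0], index=list(self.methods))


def fit_ensemble(bundles: Mapping[str, TrainedModelBundle],
                 labels: pd.Series, seed: int = 0) -> EnsembleModel:
    """Fit the logistic ensemble on out-of-fold probabilities.

    Using out-of-fold rather than resubstitution probabilities keeps the
    integrator from simply rewarding the most overfitted base model.
    """
    methods = tuple(m for m in METHODS if m in bundles) or tuple(bundles)
    index = bundles[methods[0]].oof.index
    for m in methods[1:]:
        if not bundles[m].oof.index.equals(index):
            raise ValueError("bundles cover different drug sets")
    if not labels.index.equals(index):
        labels = labels.reindex(index)
        if labels.isna().any():
            raise ValueError("labels do not cover the bundles' drugs")
    X = pd.DataFrame({m: bundles[m].oof for m in methods})
    y = labels.to_numpy().astype(int)
    lr = LogisticRegression(C=100.0, max_iter=5000, random_state=seed)
    lr.fit(X.to_numpy(), y, sample_weight=_sample_weights(y))
    return EnsembleModel(methods=methods, model=lr)
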