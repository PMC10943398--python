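"""Biomarker selection: L1-penalised logistic regression and SVM-RFE.

Two complementary selectors are run on the candidate genes and their
intersection is reported as the key biomarker set.  The LASSO path is
scored by cross-validated deviance over a log-spaced penalty grid anchored
at the data-derived lambda_max; SVM-RFE ranks features by the squared
weights of a linear maximum-margin classifier, eliminating the weakest
features recursively, and picks the prefix size with the smallest
cross-validated misclassification error (ties broken toward fewer genes).
The convex solvers come from scikit-learn; the penalty grid, fold logic,
elimination loop and subset-size selection are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ArgumentError, DataError

__all__ = ["SelectionResult", "lasso_select", "svm_rfe_rank", "intersect_selections", "select_biomarkers"]

_EPS = 1e-12


@dataclass
class SelectionResult:
    """Outcome of the dual selection run."""

    lasso_selected: set[str]
    lasso_lambda: float
    svmrfe_ranking: list[str]
    svmrfe_selected: set[str]
    key_genes: set[str]
    cv_folds: int
    seed: int


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


def _check_labels(y: np.ndarray, k_folds: int) -> np.ndarray:
    y = np.asarray(y).ravel()
    classes = np.unique(y)
    if classes.size != 2:
        raise DataError("labels must contain exactly two classes")
    y01 = (y == classes.max()).astype(int)
    if min(np.bincount(y01)) < k_folds:
        raise DataError("each class needs at least k_folds samples")
    return y01


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def default_lambda_grid(X: np.ndarray, y01: np.ndarray, n_lambdas: int = 30) -> np.ndarray:
    """Log-spaced penalty grid over [1e-3, 1] x lambda_max.

    lambda_max = max_j |x_j . (y - ybar)| / n is the smallest penalty at
    which the L1-penalised logistic null model has zero gradient, i.e. the
    point where every coefficient is shrunk away.
    """
    Z = _standardize(X)
    n = Z.shape[0]
    lam_max = np.abs(Z.T @ (y01 - y01.mean())).max() / n
    lam_max = max(lam_max, _EPS)
    return lam_max * np.logspace(0.0, -3.0, n_lambdas)


def _fit_l1(Z: np.ndarray, y01: np.ndarray, lam: float) -> LogisticRegression:
    C = 1.0 / max(Z.shape[0] * lam, _EPS)
    model = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, tol=1e-8, random_state=0
    )
    model.fit(Z, y01)
    return model


def _deviance(model: LogisticRegression, Z: np.ndarray, y01: np.ndarray) -> float:
    p = model.predict_proba(Z)[:, 1]
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-2.0 * np.mean(y01 * np.log(p) + (1 - y01) * np.log(1 - p)))


def lasso_select(
    X,
    y,
    lambda_grid=None,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[set[str], float]:
    """Select genes with nonzero L1-logistic coefficients at the CV-best penalty.

    Features are standardized internally; the penalty minimizing mean
    cross-validated deviance over seeded stratified folds is chosen, the
    model is refit on all samples at that penalty, and genes with nonzero
    coefficients are returned together with the chosen lambda.
    """
    Xm, names = _as_matrix(X)
    y01 = _check_labels(np.asarray(y), k_folds)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(Xm, y01)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ArgumentError("empty lambda grid")
    if (lambda_grid <= 0).any():
        raise ArgumentError("penalties must be positive")

    Z = _standardize(Xm)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(Z, y01))
    mean_dev = np.empty(lambda_grid.size)
    for i, lam in enumerate(lambda_grid):
        devs = []
        for tr, te in folds:
            model = _fit_l1(Z[tr], y01[tr], lam)
            devs.append(_deviance(model, Z[te], y01[te]))
        mean_dev[i] = np.mean(devs)
    best = int(np.argmin(mean_dev))
    lam = float(lambda_grid[best])
    final = _fit_l1(Z, y01, lam)
    coef = final.coef_.ravel()
    selected = {names[j] for j in np.nonzero(np.abs(coef) > 0)[0]}
    return selected, lam


def _rfe_path(
    Z: np.ndarray,
    y01: np.ndarray,
    elimination_step: int,
    C: float,
    Z_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
) -> tuple[list[int], dict[int, float]]:
    """One recursive-elimination pass.

    Returns the removal order (weakest removed first) and, when a test split
    is supplied, the per-surviving-set-size misclassification error of the
    model fit at that size — the fit used for elimination doubles as the
    honest scorer for the held-out split.
    """
    p = Z.shape[1]
    remaining = list(range(p))
    removal_order: list[int] = []
    errors: dict[int, float] = {}
    while remaining:
        svm = SVC(kernel="linear", C=C)
        svm.fit(Z[:, remaining], y01)
        if Z_test is not None:
            pred = svm.predict(Z_test[:, remaining])
            errors[len(remaining)] = float(np.mean(pred != y_test))
        if len(remaining) == 1:
            break
        w2 = (svm.coef_.ravel()) ** 2
        k = min(elimination_step, len(remaining) - 1)
        order = np.argsort(w2, kind="mergesort")[:k]  # weakest first, stable
        dropped = [remaining[j] for j in order]
        removal_order.extend(dropped)
        drop_set = set(dropped)
        remaining = [j for j in remaining if j not in drop_set]
    return removal_order, errors


def svm_rfe_rank(
    X,
    y,
    elimination_step: int = 1,
    k_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> tuple[list[str], set[str]]:
    """Rank features by recursive elimination and pick the CV-best prefix.

    At each round a linear SVM is fit on the surviving (standardized)
    features; the ``elimination_step`` features with the smallest squared
    weights are dropped (never past a single survivor).  The ranking is the
    reverse removal order of the all-sample pass.  The retained subset size
    is chosen by nested cross-validation: the elimination is repeated inside
    each stratified training fold and every visited size is scored on the
    held-out fold, so the error curve is free of selection bias; the size
    minimizing mean error wins (smaller size on ties), and the selected set
    is that prefix of the ranking.
    """
    if elimination_step < 1:
        raise ArgumentError("elimination_step must be >= 1")
    Xm, names = _as_matrix(X)
    y01 = _check_labels(np.asarray(y), k_folds)
    Z = _standardize(Xm)
    p = Z.shape[1]
    if p == 1:
        return [names[0]], {names[0]}

    removal_order, _ = _rfe_path(Z, y01, elimination_step, C)
    last = [j for j in range(p) if j not in set(removal_order)]
    ranking_idx = last + removal_order[::-1]
    ranking = [names[j] for j in ranking_idx]

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_errors: list[dict[int, float]] = []
    for tr, te in skf.split(Z, y01):
        _, errs = _rfe_path(Z[tr], y01[tr], elimination_step, C, Z[te], y01[te])
        fold_errors.append(errs)
    sizes = sorted(set.intersection(*(set(e) for e in fold_errors)))
    mean_err = {s: float(np.mean([e[s] for e in fold_errors])) for s in sizes}
    best_size = min(sizes, key=lambda s: (mean_err[s], s))
    return ranking, set(ranking[:best_size])


def intersect_selections(a: set, b: set) -> set:
    """Exact intersection of the two selectors' gene sets."""
    return set(a) & set(b)


def select_biomarkers(
    X,
    y,
    lambda_grid=None,
    elimination_step: int = 1,
    k_folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Run both selectors and intersect them into the key biomarker set."""
    lasso_sel, lam = lasso_select(X, y, lambda_grid=lambda_grid, k_folds=k_folds, seed=seed)
    ranking, svm_sel = svm_rfe_rank(
        X, y, elimination_step=elimination_step, k_folds=k_folds, seed=seed
    )
    return SelectionResult(
        lasso_selected=lasso_sel,
        lasso_lambda=lam,
        svmrfe_ranking=ranking,
        svmrfe_selected=svm_sel,
        key_genes=intersect_selections(lasso_sel, svm_sel),
        cv_folds=k_folds,
        seed=seed,
    )
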