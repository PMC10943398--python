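"""ROC/AUC diagnostics for single genes and combined gene panels.

The AUC is computed by the rank (Mann-Whitney) formulation — the
probability that a random case scores above a random control, with tied
scores contributing 1/2 — and the ROC polyline is swept over all distinct
thresholds; the trapezoidal area of that polyline equals the rank AUC
exactly and serves as an internal cross-check.  The combined panel score
is the linear predictor of an (effectively) unpenalised logistic model fit
on a training cohort; a vanishing ridge keeps the fit defined under
perfect separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

from .errors import DataError

__all__ = ["RocResult", "roc_auc", "combined_panel_score"]

RIDGE_C = 1e6  # near-unpenalised; stabilizes separable fits


@dataclass
class RocResult:
    gene_or_model: str
    auc: float
    curve: np.ndarray  # (points, 2): fpr, tpr
    n_pos: int
    n_neg: int


def roc_auc(scores, labels, name: str = "score") -> RocResult:
    """Rank-formulation AUC and the threshold-swept ROC polyline."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).ravel()
    classes = np.unique(y)
    if classes.size != 2:
        raise DataError("labels must contain exactly two classes")
    pos = y == classes.max()
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = stats.rankdata(s)  # average ranks: ties count 1/2
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(pos.astype(int), s, drop_intermediate=False)
    curve = np.column_stack([fpr, tpr])
    return RocResult(name, float(auc), curve, n_pos, n_neg)


def combined_panel_score(
    X_train, y_train, X_eval, genes, mode: str = "logistic"
) -> np.ndarray:
    """Per-sample panel score on the evaluation cohort.

    ``logistic`` (default): linear predictor of a logistic model fit on the
    training samples restricted to the panel.  ``mean_z``: mean of the
    panel genes after standardizing each by its training mean/sd, signed by
    the training-case direction of the gene — a model-free alternative.
    """
    genes = list(genes)
    for g in genes:
        if g not in X_train.columns or g not in X_eval.columns:
            raise DataError(f"panel gene {g!r} missing from an expression matrix")
    Xt = X_train[genes].to_numpy(dtype=float)
    Xe = X_eval[genes].to_numpy(dtype=float)
    y = np.asarray(y_train).ravel()
    classes = np.unique(y)
    if classes.size != 2:
        raise DataError("training labels must contain exactly two classes")
    y01 = (y == classes.max()).astype(int)
    if mode == "logistic":
        model = LogisticRegression(l1_ratio=0.0, C=RIDGE_C, solver="lbfgs", max_iter=10_000)
        model.fit(Xt, y01)
        return model.decision_function(Xe)
    if mode == "mean_z":
        mu, sd = Xt.mean(axis=0), Xt.std(axis=0)
        sd[sd == 0] = 1.0
        sign = np.sign(Xt[y01 == 1].mean(axis=0) - Xt[y01 == 0].mean(axis=0))
        sign[sign == 0] = 1.0
        return (((Xe - mu) / sd) * sign).mean(axis=1)
    raise ValueError(f"unknown mode {mode!r}")
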