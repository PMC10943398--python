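"""Cohort merging, batch correction, differential expression and panel intersection.

Differential expression is a per-gene two-sample t contrast on log2 values
with Benjamini-Hochberg control of the false-discovery rate.  An optional
empirical-Bayes moderation shrinks gene-wise variances toward a common
prior fitted to all genes, which stabilizes the statistic when per-group
sample sizes are small.  A gene is called differential when its linear
fold change exceeds the threshold (default 1.2, i.e. |log2FC| > log2 1.2)
and its adjusted p-value falls below alpha.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import CASE, CONTROL, DEResult, ExpressionMatrix
from .errors import ArgumentError, DataError

__all__ = [
    "merge_and_correct",
    "differential_expression",
    "bh_adjust",
    "intersect_panel",
    "moderated_ttest",
]


def merge_and_correct(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Merge cohorts on their shared genes and equalize per-batch gene means.

    The output gene set is the intersection of the input gene sets.  For
    every gene, each batch's mean is shifted to the overall (grand) mean, so
    after correction per-batch means agree and the per-gene grand mean is
    preserved.  Within-batch deviations are untouched; this is a pure
    location adjustment.
    """
    if not matrices:
        raise ArgumentError("need at least one matrix")
    shared: list[str] = list(matrices[0].values.columns)
    for m in matrices[1:]:
        cols = set(m.values.columns)
        shared = [g for g in shared if g in cols]
    if not shared:
        raise DataError("empty gene intersection across input matrices")

    values = pd.concat([m.values[shared] for m in matrices], axis=0)
    group = pd.concat([m.group for m in matrices])
    batch = pd.concat([m.batch for m in matrices])
    if values.index.has_duplicates:
        raise DataError("duplicate sample identifiers across matrices")

    counts = batch.value_counts()
    if (counts < 2).any():
        small = sorted(counts.index[counts < 2])
        raise DataError(f"batches with fewer than 2 samples: {small}")

    X = values.to_numpy(dtype=float)
    grand = X.mean(axis=0)
    b = batch.to_numpy()
    for label in counts.index:
        mask = b == label
        X[mask, :] += grand - X[mask, :].mean(axis=0)
    corrected = pd.DataFrame(X, index=values.index, columns=values.columns)
    return ExpressionMatrix(corrected, group, batch)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    Sorted p-values are multiplied by n/rank, a running minimum is taken
    from the largest rank down, and results are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ArgumentError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ArgumentError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled-inverse-chi-square variance prior.

    Works on log sample variances: under the hierarchical model,
    log(s²) - digamma(df/2) + log(df/2) has mean log(s0²) + digamma(d0/2)
    - log(d0/2) and excess variance trigamma(d0/2) beyond trigamma(df/2).
    Returns (d0, s0²); d0 = inf means total shrinkage to s0².
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return 0.0, float(np.median(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ev = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if ev <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
        return d0, s0_sq
    d0 = 2.0 * _trigamma_inverse(ev)
    s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x  # good starting point: trigamma(y) ~ 1/y + 1/(2y^2)
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderated_ttest(
    Xa: np.ndarray, Xb: np.ndarray, prior_df: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t per column with variance shrinkage.

    Gene-wise pooled variances are shrunk toward a common prior variance
    s0² with weight ``prior_df`` (estimated from the data when None):
    s²_post = (d0·s0² + d·s²)/(d0 + d), and the statistic is referred to a
    t distribution on d0 + d degrees of freedom.  ``prior_df=0`` recovers
    the ordinary pooled two-sample t exactly.

    Returns (t, p, log2fc-like mean difference) arrays.
    """
    na, nb = Xa.shape[0], Xb.shape[0]
    if na < 2 or nb < 2:
        raise DataError("need at least 2 samples per group")
    ma, mb = Xa.mean(axis=0), Xb.mean(axis=0)
    diff = ma - mb
    df = na + nb - 2
    ss = ((Xa - ma) ** 2).sum(axis=0) + ((Xb - mb) ** 2).sum(axis=0)
    s2 = ss / df
    if prior_df is None:
        d0, s0_sq = _fit_variance_prior(s2, df)
    else:
        d0, s0_sq = float(prior_df), float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    t = np.where((se == 0) & (diff == 0), 0.0, t)
    return t, p, diff


def _welch_ttest(Xa: np.ndarray, Xb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    na, nb = Xa.shape[0], Xb.shape[0]
    ma, mb = Xa.mean(axis=0), Xb.mean(axis=0)
    va = Xa.var(axis=0, ddof=1)
    vb = Xb.var(axis=0, ddof=1)
    diff = ma - mb
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, diff / np.sqrt(np.where(se2 > 0, se2, 1.0)), 0.0)
        dfw = np.where(
            se2 > 0,
            se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)),
            1.0,
        )
    p = 2.0 * stats.t.sf(np.abs(t), dfw)
    # zero variance in both groups: equal means -> null; unequal -> infinite evidence
    degenerate = se2 == 0
    t = np.where(degenerate & (diff != 0), np.inf * np.sign(diff), t)
    p = np.where(degenerate & (diff != 0), 0.0, p)
    p = np.where(degenerate & (diff == 0), 1.0, p)
    return t, p, diff


def differential_expression(
    matrix: ExpressionMatrix,
    fc_threshold: float = 1.2,
    alpha: float = 0.05,
    moderation: bool = True,
    use_adjusted: bool = True,
) -> list[DEResult]:
    """Call differential genes between cases and controls.

    The fold-change gate is linear: a gene passes when
    ``|log2fc| > log2(fc_threshold)``.  The significance gate uses the
    BH-adjusted p-value by default (``use_adjusted=False`` gates on the raw
    p instead).  ``moderation=False`` uses the Welch unequal-variance t;
    ``moderation=True`` uses the empirical-Bayes shrunken pooled t.
    """
    if fc_threshold <= 1.0:
        raise ArgumentError("fc_threshold must exceed 1")
    if not 0.0 < alpha < 1.0:
        raise ArgumentError("alpha must lie in (0, 1)")
    mask = matrix.case_mask()
    Xa = matrix.values.to_numpy(dtype=float)[mask]
    Xb = matrix.values.to_numpy(dtype=float)[~mask]
    if Xa.shape[0] < 2 or Xb.shape[0] < 2:
        raise DataError("need at least 2 samples per group")
    if moderation:
        t, p, lfc = moderated_ttest(Xa, Xb)
    else:
        t, p, lfc = _welch_ttest(Xa, Xb)
    p_adj = bh_adjust(p)
    gate_p = p_adj if use_adjusted else p
    lfc_cut = np.log2(fc_threshold)
    results = []
    for j, gene in enumerate(matrix.gene_ids):
        is_de = bool((abs(lfc[j]) > lfc_cut) and (gate_p[j] < alpha))
        results.append(
            DEResult(
                gene=gene,
                log2fc=float(lfc[j]),
                t_stat=float(t[j]),
                p_raw=float(p[j]),
                p_adj=float(p_adj[j]),
                is_de=is_de,
                direction="up" if lfc[j] >= 0 else "down",
            )
        )
    return results


def intersect_panel(de_results: list[DEResult], panel: set[str]) -> set[str]:
    """Differential genes that are members of the curated panel."""
    return {r.gene for r in de_results if r.is_de} & set(panel)
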