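"""Gene / immune-cell-fraction correlation and group contrasts.

Fractions arrive from an external deconvolution (e.g. a 22-cell-type
signature-based estimate per sample) together with a per-sample
goodness-of-fit p-value; samples failing the fit are filtered out first.
Gene-fraction association uses Spearman rank correlation with the
t-approximation p-value; group contrasts use the two-sided Wilcoxon
rank-sum test, exact by enumeration when both groups have at most ten
tie-free observations, and the tie-corrected normal approximation
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FractionTable
from .errors import ArgumentError, DataError
from .preprocess import bh_adjust

__all__ = [
    "GeneCellCorrelation",
    "filter_samples",
    "spearman_correlate",
    "rank_sum_test",
    "compare_groups",
]

EXACT_MAX_N = 10


@dataclass
class GeneCellCorrelation:
    gene: str
    cell_type: str
    rho: float
    p: float
    p_adj: float = float("nan")
    valid: bool = True


def filter_samples(fractions: FractionTable, alpha: float = 0.05) -> FractionTable:
    """Keep samples whose deconvolution p-value is below ``alpha``."""
    keep = fractions.deconv_p < alpha
    return FractionTable(
        fractions.fractions.loc[keep].copy(), fractions.deconv_p.loc[keep].copy()
    )


def spearman_correlate(
    gene_values: pd.Series,
    fractions: FractionTable,
    gene: str = "gene",
) -> tuple[list[GeneCellCorrelation], GeneCellCorrelation | None, GeneCellCorrelation | None]:
    """Spearman rho of one gene against every cell-type fraction.

    Ranks are averaged over ties; p-values come from the t-approximation on
    rho.  Constant inputs yield a flagged (invalid) record that is excluded
    from the returned extremes.  P-values are BH-adjusted across the cell
    types of this gene.  Returns (records, max-rho pair, min-rho pair).
    """
    common = fractions.fractions.index.intersection(gene_values.index)
    if len(common) < 4:
        raise DataError("need at least 4 paired observations")
    g = gene_values.loc[common].to_numpy(dtype=float)
    records: list[GeneCellCorrelation] = []
    for ct in fractions.cell_types:
        f = fractions.fractions.loc[common, ct].to_numpy(dtype=float)
        if np.ptp(g) == 0 or np.ptp(f) == 0:
            records.append(GeneCellCorrelation(gene, ct, float("nan"), float("nan"), valid=False))
            continue
        rho, p = stats.spearmanr(g, f)
        records.append(GeneCellCorrelation(gene, ct, float(rho), float(p)))
    valid = [r for r in records if r.valid]
    if valid:
        adj = bh_adjust([r.p for r in valid])
        for r, a in zip(valid, adj):
            r.p_adj = float(a)
    top = max(valid, key=lambda r: r.rho, default=None)
    bottom = min(valid, key=lambda r: r.rho, default=None)
    return records, top, bottom


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum statistic (Mann-Whitney U of ``a``) and p.

    Exact null enumeration when both groups have <= 10 observations and no
    ties across the pooled sample; tie-corrected normal approximation
    (without continuity correction) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:  # all values identical: no evidence either way
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    exact = (a.size <= EXACT_MAX_N) and (b.size <= EXACT_MAX_N) and not has_ties
    res = stats.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_groups(fractions: FractionTable, labels: pd.Series) -> pd.DataFrame:
    """Wilcoxon rank-sum contrast of every cell type between two groups.

    ``labels`` is a binary per-sample series aligned with the fraction
    table.  Returns a DataFrame (cell_type, statistic, p, p_adj).
    """
    labels = labels.reindex(fractions.fractions.index)
    if labels.isna().any():
        raise DataError("every sample needs a group label")
    values = sorted(pd.unique(labels))
    if len(values) != 2:
        raise DataError("labels must define exactly two non-empty groups")
    mask = (labels == values[0]).to_numpy()
    rows = []
    for ct in fractions.cell_types:
        f = fractions.fractions[ct].to_numpy(dtype=float)
        stat, p = rank_sum_test(f[mask], f[~mask])
        rows.append({"cell_type": ct, "statistic": stat, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
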