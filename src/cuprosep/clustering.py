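"""Resampling consensus clustering for case-sample subtyping.

For each candidate cluster number k, the samples are repeatedly subsampled
(without replacement) and clustered; the consensus matrix entry (i, j) is
the fraction of co-sampled runs in which i and j landed in the same
cluster.  A stable k produces a near-binary consensus matrix, i.e. a
consensus-value CDF that is flat between 0 and 1.  Two k-selection rules
are provided: minimal ambiguity (the PAC criterion — fraction of consensus
values in an ambiguous band, ties toward smaller k; the default, a direct
formalization of "minimum CDF fluctuation") and the delta-area elbow
(largest k whose relative area gain exceeds a threshold).  Final labels
come from hierarchical clustering of 1 - consensus at the chosen k.

The inner clusterer is agglomerative with average linkage on
1 - Pearson-correlation distance between samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA

from .containers import ExpressionMatrix
from .errors import ArgumentError, DataError
from .immune import rank_sum_test
from .preprocess import bh_adjust

__all__ = ["ConsensusResult", "consensus_cluster", "subcluster_contrast", "pca_embed"]

log = logging.getLogger(__name__)

PAC_BAND = (0.1, 0.9)


@dataclass
class ConsensusResult:
    consensus: dict[int, np.ndarray]  # per-k samples x samples consensus matrix
    cdf: dict[int, tuple[np.ndarray, np.ndarray]]  # per-k (sorted values, ecdf)
    area: dict[int, float]  # per-k area under the consensus CDF
    delta_area: dict[int, float]  # relative area increase vs previous k
    pac: dict[int, float]  # per-k proportion of ambiguous consensus values
    chosen_k: int
    labels: pd.Series  # per-sample cluster id, 1-based
    sample_ids: list[str]
    params: dict


def _correlation_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between sample rows, clipped to [0, 2]."""
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    D = 1.0 - corr
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def _agglomerative(D: np.ndarray, k: int) -> np.ndarray:
    model = AgglomerativeClustering(n_clusters=k, metric="precomputed", linkage="average")
    return model.fit_predict(D)


def consensus_cluster(
    X,
    k_range=range(2, 7),
    H: int = 1000,
    p_item: float = 0.8,
    seed: int = 0,
    chooser: str = "pac",
    delta_threshold: float = 0.1,
) -> ConsensusResult:
    """Consensus-cluster samples over a range of k and select the stable k.

    Parameters
    ----------
    X
        samples x genes values (DataFrame or array).
    k_range
        Candidate cluster numbers, all >= 2.
    H
        Number of subsampling repetitions per k (a warning is logged below
        10; production default 1000).
    p_item
        Fraction of samples drawn (without replacement) per repetition.
    chooser
        ``"pac"`` (default): k minimizing the proportion of ambiguous
        consensus values in (0.1, 0.9), ties toward smaller k.
        ``"delta_area"``: largest k whose relative CDF-area increase
        exceeds ``delta_threshold``.
    """
    if isinstance(X, pd.DataFrame):
        sample_ids = list(X.index)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        sample_ids = [f"S{i:04d}" for i in range(Xm.shape[0])]
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ArgumentError("empty k range")
    if min(ks) < 2:
        raise ArgumentError("all k must be >= 2")
    n = Xm.shape[0]
    if n < 2 * max(ks):
        raise DataError("need at least 2*max(k) samples")
    if not 0.0 < p_item <= 1.0:
        raise ArgumentError("p_item must lie in (0, 1]")
    if H < 10:
        log.warning("H=%d subsamples is very low; consensus estimates will be noisy", H)

    rng = np.random.default_rng(seed)
    m_sub = math.ceil(p_item * n)
    iu = np.triu_indices(n, k=1)

    consensus: dict[int, np.ndarray] = {}
    cdf: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    area: dict[int, float] = {}
    pac: dict[int, float] = {}
    for k in ks:
        co_cluster = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        for _ in range(H):
            idx = rng.choice(n, size=m_sub, replace=False)
            D = _correlation_distance(Xm[idx])
            lab = _agglomerative(D, k)
            ind = np.zeros((n,), dtype=bool)
            ind[idx] = True
            co_sample += np.outer(ind, ind)
            for c in range(k):
                members = idx[lab == c]
                sel = np.zeros((n,), dtype=bool)
                sel[members] = True
                co_cluster += np.outer(sel, sel)
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(co_sample > 0, co_cluster / np.where(co_sample > 0, co_sample, 1.0), 0.0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0
        consensus[k] = M
        vals = np.sort(M[iu])
        ecdf = np.arange(1, vals.size + 1) / vals.size
        cdf[k] = (vals, ecdf)
        area[k] = float(1.0 - vals.mean())  # integral of the ECDF over [0, 1]
        lo, hi = PAC_BAND
        pac[k] = float(np.mean((vals > lo) & (vals < hi)))

    delta_area: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta_area[k] = area[k]
        else:
            prev = area[ks[i - 1]]
            delta_area[k] = (area[k] - prev) / prev if prev > 0 else float("inf")

    if chooser == "pac":
        chosen_k = min(ks, key=lambda k: (pac[k], k))
    elif chooser == "delta_area":
        above = [k for k in ks if delta_area[k] > delta_threshold]
        chosen_k = max(above) if above else ks[0]
    else:
        raise ArgumentError(f"unknown chooser {chooser!r}")

    final = _agglomerative(1.0 - consensus[chosen_k], chosen_k)
    labels = pd.Series(final + 1, index=sample_ids)
    return ConsensusResult(
        consensus=consensus,
        cdf=cdf,
        area=area,
        delta_area=delta_area,
        pac=pac,
        chosen_k=chosen_k,
        labels=labels,
        sample_ids=sample_ids,
        params={"H": H, "p_item": p_item, "linkage": "average",
                "distance": "1 - pearson", "seed": seed, "chooser": chooser},
    )


def subcluster_contrast(X, labels: pd.Series, genes) -> pd.DataFrame:
    """Per-gene rank-sum contrast between exactly two subclusters.

    Returns a DataFrame (gene, statistic, p, p_adj), BH-adjusted across the
    listed genes.
    """
    if isinstance(X, ExpressionMatrix):
        X = X.values
    labels = labels.reindex(X.index)
    if labels.isna().any():
        raise DataError("every sample needs a cluster label")
    values = sorted(pd.unique(labels))
    if len(values) != 2:
        raise ArgumentError("exactly 2 clusters required")
    mask = (labels == values[0]).to_numpy()
    rows = []
    for g in genes:
        if g not in X.columns:
            raise DataError(f"gene {g!r} absent from expression")
        v = X[g].to_numpy(dtype=float)
        stat, p = rank_sum_test(v[mask], v[~mask])
        rows.append({"gene": g, "statistic": stat, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def pca_embed(X, n_components: int = 2) -> np.ndarray:
    """Project samples onto the top principal axes of the centered matrix."""
    if n_components <= 0:
        raise ArgumentError("n_components must be positive")
    if isinstance(X, (pd.DataFrame,)):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if n_components > min(X.shape):
        raise ArgumentError("n_components exceeds matrix rank bound")
    return PCA(n_components=n_components, svd_solver="full").fit_transform(X)
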