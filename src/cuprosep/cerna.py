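"""Competing-endogenous-RNA (ceRNA) network inference.

An lncRNA and an mRNA "compete" when they share a surprising number of
miRNA partners and are positively co-expressed.  For a pair sharing x of
the mRNA's n and the lncRNA's m miRNAs out of a universe of N distinct
miRNAs, the sharing surprise is the hypergeometric upper tail

    P = 1 - sum_{k=0}^{x} C(m,k) C(N-m,n-k) / C(N,n)

(the probability of sharing strictly more than x partners by chance; the
conventional "at least x" tail, summing to x-1, is also available).
Retained pairs must pass the hypergeometric gate (default alpha 0.01) and
a Pearson co-expression gate (r > 0.3 at p < 0.01).  The assembled graph
contains the retained competing pairs, their shared miRNAs and the
miRNA-target edges; lncRNA hubs are ranked by degree, then unnormalized
shortest-path betweenness, then identifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, InteractionTable
from .errors import ArgumentError, DataError

__all__ = [
    "CeRNACandidate",
    "hypergeom_competing_test",
    "coexpression_pcc",
    "build_cerna_network",
    "rank_hubs",
]

log = logging.getLogger(__name__)


@dataclass
class CeRNACandidate:
    """One (lncRNA, mRNA) pair with its sharing and co-expression evidence."""

    lncrna: str
    mrna: str
    N: int
    n: int
    m: int
    x: int
    p_hyper: float
    pcc: float
    p_pcc: float
    retained: bool


def hypergeom_competing_test(
    N: int, n: int, m: int, x: int, convention: str = "as_printed"
) -> float:
    """Upper-tail hypergeometric probability of the observed miRNA sharing.

    ``as_printed`` returns P(X > x) = 1 - CDF(x); ``at_least_x`` returns
    P(X >= x) = 1 - CDF(x - 1).  Evaluated through the exact log-stable
    hypergeometric survival function, never by simulation.
    """
    for name, v in (("N", N), ("n", n), ("m", m), ("x", x)):
        if v < 0:
            raise ArgumentError(f"{name} must be non-negative")
    if n > N or m > N:
        raise ArgumentError("n and m cannot exceed N")
    if x > min(n, m):
        raise ArgumentError("x cannot exceed min(n, m)")
    dist = stats.hypergeom(M=N, n=m, N=n)
    if convention == "as_printed":
        return float(np.clip(dist.sf(x), 0.0, 1.0))
    if convention == "at_least_x":
        return float(np.clip(dist.sf(x - 1), 0.0, 1.0))
    raise ArgumentError(f"unknown convention {convention!r}")


def coexpression_pcc(x_values, y_values) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-reference p (df = n-2).

    Raises :class:`DataError` on fewer than 4 paired finite observations or
    a zero-variance vector (the undefined-correlation case).
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ArgumentError("x and y must be equal-length vectors")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 4:
        raise DataError("need at least 4 paired finite observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def build_cerna_network(
    mrna_mirna: InteractionTable,
    lncrna_mirna: InteractionTable,
    expression: pd.DataFrame | ExpressionMatrix,
    key_genes,
    alpha_hyper: float = 0.01,
    pcc_min: float = 0.3,
    alpha_pcc: float = 0.01,
    convention: str = "as_printed",
    adjust_hyper: bool = False,
) -> tuple[list[CeRNACandidate], nx.Graph]:
    """Score all (lncRNA, key mRNA) pairs and assemble the retained network.

    Candidates are every pair sharing at least one miRNA; N is the number
    of distinct miRNAs across both interaction tables.  A pair is retained
    when its hypergeometric tail falls below ``alpha_hyper`` (optionally
    BH-adjusted across candidates) and its co-expression passes
    ``pcc > pcc_min`` at ``p < alpha_pcc``.  The graph holds retained
    pairs, their shared miRNAs, the miRNA-target edges, and the competing
    lncRNA-mRNA links; node attributes carry type, degree and betweenness.
    """
    key_genes = set(key_genes)
    if not key_genes:
        raise ArgumentError("key_genes must be non-empty")
    if isinstance(expression, ExpressionMatrix):
        expression = expression.values

    universe = mrna_mirna.mirnas | lncrna_mirna.mirnas
    N = len(universe)

    mrna_sets = {
        t: mrna_mirna.mirnas_of(t) for t in mrna_mirna.targets("mRNA") if t in key_genes
    }
    for g in sorted(key_genes - set(mrna_sets)):
        log.info("key gene %s absent from the mRNA interaction table; skipped", g)
    lnc_sets = {t: lncrna_mirna.mirnas_of(t) for t in lncrna_mirna.targets("lncRNA")}

    candidates: list[CeRNACandidate] = []
    for lnc, lnc_mirnas in lnc_sets.items():
        for mrna, mrna_mirnas in mrna_sets.items():
            shared = lnc_mirnas & mrna_mirnas
            if not shared:
                continue
            n, m, x = len(mrna_mirnas), len(lnc_mirnas), len(shared)
            p_hyper = hypergeom_competing_test(N, n, m, x, convention=convention)
            if lnc in expression.columns and mrna in expression.columns:
                try:
                    pcc, p_pcc = coexpression_pcc(expression[lnc], expression[mrna])
                except DataError:
                    pcc, p_pcc = float("nan"), float("nan")
            else:
                log.info("pair (%s, %s) missing from expression; excluded from PCC stage", lnc, mrna)
                pcc, p_pcc = float("nan"), float("nan")
            candidates.append(
                CeRNACandidate(lnc, mrna, N, n, m, x, p_hyper, pcc, p_pcc, retained=False)
            )

    if candidates:
        p_h = np.array([c.p_hyper for c in candidates])
        if adjust_hyper:
            from .preprocess import bh_adjust

            p_h = bh_adjust(p_h)
        for c, ph in zip(candidates, p_h):
            c.retained = bool(
                (ph < alpha_hyper)
                and np.isfinite(c.pcc)
                and (c.pcc > pcc_min)
                and (c.p_pcc < alpha_pcc)
            )

    G = nx.Graph()
    for c in candidates:
        if not c.retained:
            continue
        G.add_node(c.lncrna, kind="lncRNA")
        G.add_node(c.mrna, kind="mRNA")
        G.add_edge(c.lncrna, c.mrna, kind="competing")
        for mi in sorted(lnc_sets[c.lncrna] & mrna_sets[c.mrna]):
            G.add_node(mi, kind="miRNA")
            G.add_edge(mi, c.lncrna, kind="interaction")
            G.add_edge(mi, c.mrna, kind="interaction")
    _annotate(G)
    return candidates, G


def _annotate(G: nx.Graph) -> None:
    bc = nx.betweenness_centrality(G, normalized=False) if len(G) else {}
    for node in G.nodes:
        G.nodes[node]["degree"] = G.degree[node]
        G.nodes[node]["betweenness"] = float(bc.get(node, 0.0))


def rank_hubs(network: nx.Graph) -> list[tuple[str, int, float]]:
    """lncRNA nodes sorted by (degree desc, betweenness desc, id asc).

    Betweenness is unnormalized shortest-path betweenness with even
    splitting over equal-length paths; the first entry is the hub.
    Returns (node, degree, betweenness) triples.
    """
    if len(network) and any(
        "degree" not in d or "betweenness" not in d for _, d in network.nodes(data=True)
    ):
        _annotate(network)
    lncs = [
        (node, d["degree"], d["betweenness"])
        for node, d in network.nodes(data=True)
        if d.get("kind") == "lncRNA"
    ]
    return sorted(lncs, key=lambda r: (-r[1], -r[2], r[0]))
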