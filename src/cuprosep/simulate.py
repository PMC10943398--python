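"""Synthetic cohorts, immune fractions and interaction tables with known truth.

Every generator is a pure function of its arguments including the seed, so
downstream stages can be validated against planted ground truth without any
external data.  The cohort generator emulates a two-batch case/control
microarray study on the log2 scale: Gaussian baseline gene means, additive
per-batch offsets, i.i.d. Gaussian noise, a planted set of differential
genes, a curated-style gene panel containing a handful of planted biomarker
("key") genes, and a two-subcluster structure among the cases driven by a
mean shift of those key genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, ExpressionMatrix, FractionTable, InteractionTable
from .errors import ArgumentError

BASELINE_MEAN = 7.0  # typical log2 microarray intensity
BASELINE_SD = 2.0
DEFAULT_PANEL_SIZE = 63  # curated cuproptosis panel size
DEFAULT_N_KEY = 6  # planted biomarker genes
SUBCLUSTER_SHIFT = 2.0  # log2 shift separating the two case subclusters


@dataclass
class CohortTruth:
    """Ground truth planted by :func:`simulate_cohort`.

    Invariants: ``key_genes ⊆ panel_genes ∩ de_genes``; subcluster labels
    exist only for case samples; every sample carries one batch label.
    """

    de_genes: set[str]
    panel_genes: set[str]
    key_genes: set[str]
    subcluster_labels: pd.Series  # index = case sample ids, values in {1, 2}
    batch_labels: pd.Series  # index = all sample ids
    effect_sizes: pd.Series  # index = de genes, signed log2 shift


@dataclass
class CeRNATruth:
    """Ground truth planted by :func:`simulate_interactions`."""

    planted_pairs: list[tuple[str, str]]  # (lncRNA, mRNA)
    mirna_universe_size: int
    background_sharing_rate: float
    planted_pcc: float


def simulate_cohort(
    n_case: int,
    n_control: int,
    n_genes: int,
    de_fraction: float,
    lfc_mean: float,
    batch_count: int,
    batch_sd: float,
    noise_sd: float,
    seed: int,
    panel_size: int = DEFAULT_PANEL_SIZE,
    n_key: int = DEFAULT_N_KEY,
    subcluster_shift: float = SUBCLUSTER_SHIFT,
) -> tuple[ExpressionMatrix, CohortTruth]:
    """Simulate a two-group log2 expression cohort with planted effects.

    Differential genes (a ``de_fraction`` share of all genes) are shifted in
    cases by a signed log2 effect whose magnitude is drawn from
    N(``lfc_mean``, 0.1·``lfc_mean``) clipped below at 0.1·``lfc_mean``.
    Samples are split round-robin over ``batch_count`` batches, each with an
    additive per-gene offset drawn from N(0, ``batch_sd``).  Key genes — a
    subset of the panel's differential genes — additionally separate the
    case samples into two subclusters via an alternating-sign shift of
    ``subcluster_shift`` log2 units in the second subcluster.
    """
    if n_case < 2 or n_control < 2:
        raise ArgumentError("need at least 2 samples per group")
    if n_genes < 10:
        raise ArgumentError("need at least 10 genes")
    if noise_sd <= 0:
        raise ArgumentError("noise_sd must be positive")
    if not 0.0 <= de_fraction <= 1.0:
        raise ArgumentError("de_fraction must lie in [0, 1]")
    if batch_count < 1:
        raise ArgumentError("batch_count must be >= 1")

    rng = np.random.default_rng(seed)
    n_samples = n_case + n_control
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    group = pd.Series([CASE] * n_case + [CONTROL] * n_control, index=samples)

    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_genes)
    X = baseline[None, :] + rng.normal(0.0, noise_sd, size=(n_samples, n_genes))

    # planted differential genes
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    magnitude = np.clip(
        rng.normal(lfc_mean, 0.1 * abs(lfc_mean), size=n_de), 0.1 * abs(lfc_mean), None
    )
    sign = rng.choice([-1.0, 1.0], size=n_de)
    effects = magnitude * sign
    X[:n_case, de_idx] += effects[None, :]

    # batches: round-robin assignment, additive per-gene offsets
    batch_ids = np.array([f"B{i % batch_count + 1}" for i in range(n_samples)])
    for b in range(batch_count):
        offs = rng.normal(0.0, batch_sd, size=n_genes) if batch_sd > 0 else np.zeros(n_genes)
        X[batch_ids == f"B{b + 1}", :] += offs[None, :]

    # curated-style panel containing the key genes
    de_set = [genes[i] for i in de_idx]
    n_key_eff = min(n_key, n_de)
    key = list(rng.choice(de_set, size=n_key_eff, replace=False)) if n_key_eff else []
    pool = [g for g in genes if g not in key]
    panel_size_eff = min(panel_size, n_genes)
    filler = list(rng.choice(pool, size=max(panel_size_eff - n_key_eff, 0), replace=False))
    panel = set(key) | set(filler)

    # two planted subclusters among cases: alternating-sign key-gene shift,
    # symmetric around the case mean so the planted case/control effect and
    # the truth table's effect_sizes stay exact
    sub = np.ones(n_case, dtype=int)
    sub[n_case // 2 :] = 2
    key_idx = [genes.index(g) for g in key]
    for j, gi in enumerate(key_idx):
        half = (subcluster_shift if j % 2 == 0 else -subcluster_shift) / 2.0
        X[:n_case, gi] += np.where(sub == 2, half, -half)

    values = pd.DataFrame(X, index=samples, columns=genes)
    batch = pd.Series(batch_ids, index=samples)
    truth = CohortTruth(
        de_genes=set(de_set),
        panel_genes=panel,
        key_genes=set(key),
        subcluster_labels=pd.Series(sub, index=samples[:n_case]),
        batch_labels=batch.copy(),
        effect_sizes=pd.Series(effects, index=de_set),
    )
    return ExpressionMatrix(values, group, batch), truth


def simulate_validation_cohort(
    truth: CohortTruth,
    n_case: int,
    n_control: int,
    n_genes: int,
    noise_sd: float,
    seed: int,
) -> ExpressionMatrix:
    """An independent cohort carrying the same planted effects as ``truth``.

    Fresh samples, baselines and noise, but the differential genes and
    their signed log2 effects are replanted unchanged, emulating a
    validation cohort drawn from the same biology (no subcluster structure
    and a single batch).  ``n_genes`` must cover every gene named in the
    truth record.
    """
    if n_case < 2 or n_control < 2:
        raise ArgumentError("need at least 2 samples per group")
    if noise_sd <= 0:
        raise ArgumentError("noise_sd must be positive")
    genes = [f"G{i:05d}" for i in range(n_genes)]
    missing = (truth.de_genes | truth.panel_genes) - set(genes)
    if missing:
        raise ArgumentError("n_genes does not cover the truth gene universe")
    rng = np.random.default_rng(seed)
    n_samples = n_case + n_control
    samples = [f"V{i:04d}" for i in range(n_samples)]
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_genes)
    X = baseline[None, :] + rng.normal(0.0, noise_sd, size=(n_samples, n_genes))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, eff in truth.effect_sizes.items():
        X[:n_case, gene_pos[g]] += eff
    values = pd.DataFrame(X, index=samples, columns=genes)
    group = pd.Series([CASE] * n_case + [CONTROL] * n_control, index=samples)
    batch = pd.Series(["B1"] * n_samples, index=samples)
    return ExpressionMatrix(values, group, batch)


def simulate_fractions(
    n_samples: int,
    n_celltypes: int,
    concentration: float,
    linked_gene_values: np.ndarray | None,
    link_strength: float,
    seed: int,
    linked_celltype: int = 0,
) -> FractionTable:
    """Simulate simplex-valued immune fractions with one linked cell type.

    Rows are symmetric-Dirichlet draws; the fraction of cell type
    ``linked_celltype`` is multiplied by ``exp(link_strength · z)`` where z
    is the standardized linked gene value, then the row is renormalized.
    This yields a rank correlation between the gene and that cell type with
    the sign of ``link_strength`` without asserting any deconvolution model.
    Deconvolution p-values are drawn Uniform(0, 0.05): synthetic samples are
    all "well deconvolved" unless the caller overwrites them.
    """
    if concentration <= 0:
        raise ArgumentError("concentration must be positive")
    if n_celltypes < 2:
        raise ArgumentError("need at least 2 cell types")
    if not -1.0 <= link_strength <= 1.0:
        raise ArgumentError("link_strength must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    F = rng.dirichlet([concentration] * n_celltypes, size=n_samples)
    if linked_gene_values is not None and link_strength != 0.0:
        g = np.asarray(linked_gene_values, dtype=float)
        if g.shape[0] != n_samples:
            raise ArgumentError("linked_gene_values length must equal n_samples")
        z = (g - g.mean()) / (g.std() if g.std() > 0 else 1.0)
        F[:, linked_celltype] *= np.exp(link_strength * z)
        F /= F.sum(axis=1, keepdims=True)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    cells = [f"CT{i:02d}" for i in range(n_celltypes)]
    fractions = pd.DataFrame(F, index=samples, columns=cells)
    deconv_p = pd.Series(rng.uniform(0.0, 0.05, size=n_samples), index=samples)
    return FractionTable(fractions, deconv_p)


def simulate_interactions(
    n_mirna: int,
    n_mrna: int,
    n_lncrna: int,
    planted_pairs: int,
    shared_per_planted: int,
    background_rate: float,
    seed: int,
    planted_pcc: float = 0.6,
    n_expr_samples: int = 60,
) -> tuple[InteractionTable, InteractionTable, CeRNATruth, pd.DataFrame]:
    """Simulate miRNA-mRNA and miRNA-lncRNA tables with planted competing pairs.

    Each planted (lncRNA, mRNA) pair shares exactly ``shared_per_planted``
    dedicated miRNAs (edges added to both tables); every other
    (miRNA, target) edge appears independently with probability
    ``background_rate``.  Expression for planted partners is bivariate
    normal with Pearson correlation ``planted_pcc``; all other transcripts
    are independent.  Returns the two tables, the truth record, and a
    samples x transcripts expression frame covering every mRNA and lncRNA.
    """
    if shared_per_planted > n_mirna:
        raise ArgumentError("cannot share more miRNAs than exist")
    if planted_pairs > n_mrna * n_lncrna:
        raise ArgumentError("more planted pairs than (lncRNA, mRNA) combinations")
    if planted_pairs > min(n_mrna, n_lncrna):
        raise ArgumentError("planted pairs must use distinct partners")
    if not 0.0 <= background_rate <= 1.0:
        raise ArgumentError("background_rate must lie in [0, 1]")
    if not 0.0 < planted_pcc <= 1.0:
        raise ArgumentError("planted_pcc must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    mirnas = [f"miR-{i:04d}" for i in range(n_mirna)]
    mrnas = [f"M{i:04d}" for i in range(n_mrna)]
    lncrnas = [f"L{i:04d}" for i in range(n_lncrna)]

    mrna_edges: set[tuple[str, str]] = set()
    lnc_edges: set[tuple[str, str]] = set()

    pairs: list[tuple[str, str]] = []
    for k in range(planted_pairs):
        lnc, mrna = lncrnas[k], mrnas[k]  # distinct partners per pair
        pairs.append((lnc, mrna))
        shared = rng.choice(n_mirna, size=shared_per_planted, replace=False)
        for mi in shared:
            mrna_edges.add((mirnas[mi], mrna))
            lnc_edges.add((mirnas[mi], lnc))

    if background_rate > 0:
        bg_m = rng.random((n_mirna, n_mrna)) < background_rate
        bg_l = rng.random((n_mirna, n_lncrna)) < background_rate
        for mi, ti in zip(*np.nonzero(bg_m)):
            mrna_edges.add((mirnas[mi], mrnas[ti]))
        for mi, ti in zip(*np.nonzero(bg_l)):
            lnc_edges.add((mirnas[mi], lncrnas[ti]))

    def _table(edges: set[tuple[str, str]], kind: str) -> InteractionTable:
        rows = sorted(edges)
        return InteractionTable(
            pd.DataFrame(
                {
                    "mirna_id": [m for m, _ in rows],
                    "target_id": [t for _, t in rows],
                    "target_kind": kind,
                }
            )
        )

    mrna_table = _table(mrna_edges, "mRNA")
    lnc_table = _table(lnc_edges, "lncRNA")

    # expression: independent N(0,1) columns, planted pairs correlated
    samples = [f"S{i:04d}" for i in range(n_expr_samples)]
    cols = mrnas + lncrnas
    E = rng.normal(size=(n_expr_samples, len(cols)))
    expr = pd.DataFrame(E, index=samples, columns=cols)
    r = planted_pcc
    for lnc, mrna in pairs:
        z = rng.normal(size=n_expr_samples)
        expr[lnc] = r * expr[mrna] + math.sqrt(1.0 - r * r) * z

    universe = mrna_table.mirnas | lnc_table.mirnas
    truth = CeRNATruth(
        planted_pairs=pairs,
        mirna_universe_size=len(universe),
        background_sharing_rate=background_rate,
        planted_pcc=planted_pcc,
    )
    return mrna_table, lnc_table, truth, expr
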