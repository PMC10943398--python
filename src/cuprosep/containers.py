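"""In-memory containers shared across the pipeline stages.

Expression values are stored samples x genes on the log2 scale, the
orientation every downstream statistical routine expects.  On disk the
transposed genes-in-rows layout conventional for expression TSVs is used
(see :mod:`cuprosep.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionMatrix:
    """A log2 expression matrix with per-sample group and batch labels.

    Parameters
    ----------
    values
        samples x genes DataFrame of finite log2 intensities; the index
        holds sample identifiers, the columns gene symbols.
    group
        Per-sample label, ``"case"`` or ``"control"``, indexed like
        ``values``.
    batch
        Per-sample batch label, indexed like ``values``.
    """

    values: pd.DataFrame
    group: pd.Series
    batch: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise DataError("duplicate sample identifiers")
        if v.columns.has_duplicates:
            raise DataError("duplicate gene identifiers")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise DataError("expression values must be finite")
        self.group = self.group.reindex(v.index)
        self.batch = self.batch.reindex(v.index)
        if self.group.isna().any():
            raise DataError("every sample needs a group label")
        if self.batch.isna().any():
            raise DataError("every sample needs a batch label")
        bad = set(self.group.unique()) - {CASE, CONTROL}
        if bad:
            raise DataError(f"unknown group labels: {sorted(bad)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def case_mask(self) -> np.ndarray:
        return (self.group == CASE).to_numpy()

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.columns]
        return ExpressionMatrix(self.values[genes].copy(), self.group.copy(), self.batch.copy())

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[sample_ids].copy(),
            self.group.loc[sample_ids].copy(),
            self.batch.loc[sample_ids].copy(),
        )

    def cases(self) -> "ExpressionMatrix":
        return self.subset_samples(self.values.index[self.case_mask()])

    def equals(self, other: "ExpressionMatrix", tol: float = 0.0) -> bool:
        if self.sample_ids != other.sample_ids or self.gene_ids != other.gene_ids:
            return False
        if not (self.group == other.group).all() or not (self.batch == other.batch).all():
            return False
        a, b = self.values.to_numpy(float), other.values.to_numpy(float)
        return bool(np.allclose(a, b, rtol=0.0, atol=tol) if tol else (a == b).all())


@dataclass
class FractionTable:
    """Immune cell-type fractions per sample with a deconvolution p-value.

    Rows live on the simplex (each sums to 1); the per-sample p-value is
    the deconvolution goodness-of-fit significance used to discard samples
    whose fraction estimates are unreliable.
    """

    fractions: pd.DataFrame
    deconv_p: pd.Series

    def __post_init__(self) -> None:
        f = self.fractions
        if f.columns.has_duplicates:
            raise DataError("cell-type names must be unique")
        sums = f.sum(axis=1).to_numpy(dtype=float)
        if len(f) and not np.allclose(sums, 1.0, atol=1e-6):
            raise DataError("fraction rows must sum to 1 (within 1e-6)")
        self.deconv_p = self.deconv_p.reindex(f.index)
        if self.deconv_p.isna().any():
            raise DataError("every sample needs a deconvolution p-value")

    @property
    def cell_types(self) -> list[str]:
        return list(self.fractions.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.index)


@dataclass
class InteractionTable:
    """Typed miRNA-target edge list (target kind ``mRNA`` or ``lncRNA``)."""

    edges: pd.DataFrame  # columns: mirna_id, target_id, target_kind

    COLUMNS = ("mirna_id", "target_id", "target_kind")

    def __post_init__(self) -> None:
        e = self.edges
        missing = [c for c in self.COLUMNS if c not in e.columns]
        if missing:
            raise DataError(f"interaction table missing columns {missing}")
        e = e.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if e.duplicated().any():
            raise DataError("duplicate interaction edges")
        if (e["mirna_id"].astype(str).str.len() == 0).any() or (
            e["target_id"].astype(str).str.len() == 0
        ).any():
            raise DataError("empty identifiers in interaction table")
        bad = set(e["target_kind"].unique()) - {"mRNA", "lncRNA"}
        if bad:
            raise DataError(f"unknown target kinds: {sorted(bad)}")
        self.edges = e

    def mirnas_of(self, target_id: str) -> set[str]:
        e = self.edges
        return set(e.loc[e["target_id"] == target_id, "mirna_id"])

    def targets(self, kind: str | None = None) -> list[str]:
        e = self.edges
        if kind is not None:
            e = e[e["target_kind"] == kind]
        return sorted(e["target_id"].unique())

    @property
    def mirnas(self) -> set[str]:
        return set(self.edges["mirna_id"])


@dataclass
class DEResult:
    """Per-gene differential-expression summary."""

    gene: str
    log2fc: float
    t_stat: float
    p_raw: float
    p_adj: float
    is_de: bool
    direction: str  # "up" | "down"


def de_results_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "log2fc": [r.log2fc for r in results],
            "t": [r.t_stat for r in results],
            "p": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "is_de": [r.is_de for r in results],
            "direction": [r.direction for r in results],
        }
    )
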