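"""Plain-text readers and writers for every format the pipeline touches.

Expression lives on disk as a genes-in-rows TSV (header row of sample
identifiers) next to a metadata TSV (sample_id, group, batch); gene panels
as GMT or one-symbol-per-line lists; interaction tables as three-column
TSVs; fraction tables as TSV with a trailing ``deconv_p`` column; networks
as GraphML.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, FractionTable, InteractionTable, de_results_frame
from .errors import ParseError


# -- expression ---------------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, expr_path, meta_path) -> None:
    matrix.values.T.to_csv(expr_path, sep="\t", index_label="gene")
    meta = pd.DataFrame(
        {"sample_id": matrix.sample_ids, "group": matrix.group.values, "batch": matrix.batch.values}
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def read_expression(expr_path, meta_path) -> ExpressionMatrix:
    try:
        values = pd.read_csv(expr_path, sep="\t", index_col=0).T
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{expr_path}: {exc}") from exc
    meta = pd.read_csv(meta_path, sep="\t")
    for col in ("sample_id", "group", "batch"):
        if col not in meta.columns:
            raise ParseError(f"{meta_path}: line 1: missing column {col!r}")
    meta = meta.set_index("sample_id")
    return ExpressionMatrix(values, meta["group"], meta["batch"].astype(str))


# -- gene panels --------------------------------------------------------------

def write_gmt(sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")


def read_gmt(path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: GMT rows need name, description, >=1 gene")
            out[parts[0]] = set(parts[2:])
    return out


def read_gene_list(path) -> set[str]:
    """Gene panel as GMT (first set) or one-symbol-per-line plain list."""
    text = Path(path).read_text().strip()
    if not text:
        return set()
    first = text.splitlines()[0]
    if "\t" in first:
        sets = read_gmt(path)
        return next(iter(sets.values()))
    return {line.strip() for line in text.splitlines() if line.strip()}


# -- interaction tables -------------------------------------------------------

def write_interactions(table: InteractionTable, path) -> None:
    table.edges.to_csv(path, sep="\t", index=False)


def read_interactions(path) -> InteractionTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in InteractionTable.COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: line 1: missing columns {missing}")
    return InteractionTable(df)


# -- fractions ----------------------------------------------------------------

def write_fractions(table: FractionTable, path) -> None:
    df = table.fractions.copy()
    df["deconv_p"] = table.deconv_p
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_fractions(path) -> FractionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "deconv_p" not in df.columns:
        raise ParseError(f"{path}: line 1: missing trailing 'deconv_p' column")
    p = df.pop("deconv_p")
    return FractionTable(df, p)


# -- DE tables ----------------------------------------------------------------

def write_de_table(results, path) -> None:
    de_results_frame(results).to_csv(path, sep="\t", index=False)


# -- networks -----------------------------------------------------------------

def write_network(G: nx.Graph, graphml_path, node_tsv=None, edge_tsv=None) -> None:
    nx.write_graphml(G, graphml_path)
    if node_tsv is not None:
        rows = [
            {"node": n, "kind": d.get("kind", ""), "degree": d.get("degree", np.nan),
             "betweenness": d.get("betweenness", np.nan), "hub_rank": d.get("hub_rank", "")}
            for n, d in G.nodes(data=True)
        ]
        pd.DataFrame(rows).to_csv(node_tsv, sep="\t", index=False)
    if edge_tsv is not None:
        rows = [{"source": u, "target": v, "kind": d.get("kind", "")} for u, v, d in G.edges(data=True)]
        pd.DataFrame(rows).to_csv(edge_tsv, sep="\t", index=False)


def read_network(graphml_path) -> nx.Graph:
    return nx.read_graphml(graphml_path)
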