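"""Configurable end-to-end pipeline over the library stages.

Stage order: preprocess -> feature selection -> {immune correlation,
consensus clustering, ceRNA network, ROC diagnostics}.  A YAML/JSON config
names the inputs, toggles stages and carries every threshold; all outputs
and a JSON run manifest (config hash, seeds, thresholds, per-stage record
counts) land in one run directory.  Deterministic stages reproduce
byte-identical outputs for an identical config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, clustering, diagnostics, feature_selection, immune, io, preprocess
from .cerna import build_cerna_network, rank_hubs
from .containers import ExpressionMatrix
from .errors import ArgumentError, DataError

log = logging.getLogger(__name__)

STAGES = ("preprocess", "select", "immune", "cluster", "cerna", "roc")


@dataclass
class PipelineConfig:
    """Everything a run needs: inputs, stage toggles, thresholds, seed."""

    expression: list[dict] = field(default_factory=list)  # [{"values": ..., "metadata": ...}]
    panel: str | None = None
    mrna_mirna: str | None = None
    lncrna_mirna: str | None = None
    cerna_expression: str | None = None  # optional separate co-expression source
    fractions: str | None = None
    validation_expression: dict | None = None  # {"values": ..., "metadata": ...}

    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGES}
    )

    fc_threshold: float = 1.2
    de_alpha: float = 0.05
    corr_min: float = 0.3
    corr_alpha: float = 0.05
    hyper_alpha: float = 0.01
    pcc_min: float = 0.3
    pcc_alpha: float = 0.01
    deconv_alpha: float = 0.05

    k_folds: int = 5
    consensus_h: int = 1000
    p_item: float = 0.8
    k_range: list[int] = field(default_factory=lambda: [2, 3, 4, 5, 6])

    seed: int = 0
    outdir: str = "cuprosep_run"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset: also parses JSON
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ArgumentError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name, lo, hi in (
            ("de_alpha", 0, 1), ("corr_alpha", 0, 1), ("hyper_alpha", 0, 1),
            ("pcc_alpha", 0, 1), ("deconv_alpha", 0, 1),
        ):
            v = getattr(self, name)
            if not lo < v < hi:
                raise ArgumentError(f"{name}={v} outside ({lo}, {hi})")
        if self.fc_threshold <= 1.0:
            raise ArgumentError("fc_threshold must exceed 1")
        if not -1.0 <= self.pcc_min <= 1.0 or not -1.0 <= self.corr_min <= 1.0:
            raise ArgumentError("correlation thresholds must lie in [-1, 1]")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ArgumentError(f"unknown stages: {sorted(unknown)}")

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _check_inputs(cfg: PipelineConfig) -> None:
    """Fail before any stage runs if an enabled stage's inputs are missing."""
    required: list[str] = []
    if cfg.enabled("preprocess"):
        if not cfg.expression:
            raise ArgumentError("preprocess enabled but no expression inputs configured")
        for pair in cfg.expression:
            required += [pair["values"], pair["metadata"]]
        if cfg.panel:
            required.append(cfg.panel)
    if cfg.enabled("immune") and cfg.fractions:
        required.append(cfg.fractions)
    if cfg.enabled("cerna"):
        if not (cfg.mrna_mirna and cfg.lncrna_mirna):
            raise ArgumentError("cerna enabled but interaction tables not configured")
        required += [cfg.mrna_mirna, cfg.lncrna_mirna]
        if cfg.cerna_expression:
            required.append(cfg.cerna_expression)
    if cfg.validation_expression:
        required += [cfg.validation_expression["values"], cfg.validation_expression["metadata"]]
    missing = [p for p in required if not Path(p).exists()]
    if missing:
        raise DataError(f"missing input files: {missing}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    cfg.validate()
    _check_inputs(cfg)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "thresholds": {
            k: getattr(cfg, k)
            for k in ("fc_threshold", "de_alpha", "corr_min", "corr_alpha",
                      "hyper_alpha", "pcc_min", "pcc_alpha", "deconv_alpha")
        },
        "stages": {},
    }

    merged: ExpressionMatrix | None = None
    key_genes: list[str] = []
    labels = None

    try:
        if cfg.enabled("preprocess"):
            mats = [io.read_expression(p["values"], p["metadata"]) for p in cfg.expression]
            merged = preprocess.merge_and_correct(mats)
            de = preprocess.differential_expression(
                merged, fc_threshold=cfg.fc_threshold, alpha=cfg.de_alpha
            )
            io.write_expression(merged, out / "merged_expression.tsv", out / "merged_metadata.tsv")
            io.write_de_table(de, out / "de_table.tsv")
            n_de = sum(r.is_de for r in de)
            log.info("preprocess: %d genes, %d differential", len(de), n_de)
            stage_info = {"genes": len(de), "de_genes": n_de}
            if cfg.panel:
                panel = io.read_gene_list(cfg.panel)
                decugs = sorted(preprocess.intersect_panel(de, panel))
                (out / "panel_intersection.txt").write_text("\n".join(decugs) + "\n")
                stage_info["panel_genes"] = len(panel)
                stage_info["panel_de_genes"] = len(decugs)
                log.info("preprocess: %d panel genes differential", len(decugs))
            manifest["stages"]["preprocess"] = stage_info

        if cfg.enabled("select"):
            if merged is None:
                raise DataError("select stage needs the preprocess stage")
            candidates = _candidate_genes(out, merged)
            X = merged.values[candidates]
            y = merged.case_mask().astype(int)
            sel = feature_selection.select_biomarkers(X, y, k_folds=cfg.k_folds, seed=cfg.seed)
            key_genes = sorted(sel.key_genes)
            report = {
                "lasso": {"selected": sorted(sel.lasso_selected), "lambda": sel.lasso_lambda},
                "svmrfe": {"ranking": sel.svmrfe_ranking, "selected": sorted(sel.svmrfe_selected)},
                "key_genes": key_genes,
            }
            (out / "selection.json").write_text(json.dumps(report, indent=2) + "\n")
            pd.DataFrame({"gene": sel.svmrfe_ranking, "rank": range(1, len(sel.svmrfe_ranking) + 1)}).to_csv(
                out / "svmrfe_ranking.tsv", sep="\t", index=False
            )
            log.info("select: %d key genes (%s)", len(key_genes), ", ".join(key_genes))
            manifest["stages"]["select"] = {"candidates": len(candidates), "key_genes": len(key_genes)}

        if cfg.enabled("immune"):
            if cfg.fractions is None:
                log.info("immune: no fraction table configured; stage skipped")
                manifest["stages"]["immune"] = {"skipped": "no fractions input"}
            else:
                if merged is None:
                    raise DataError("immune stage needs the preprocess stage")
                fr = io.read_fractions(cfg.fractions)
                fr = immune.filter_samples(fr, cfg.deconv_alpha)
                genes = key_genes or _candidate_genes(out, merged)
                cases = merged.cases()
                rows = []
                for g in genes:
                    recs, _, _ = immune.spearman_correlate(cases.values[g], fr, gene=g)
                    rows += [
                        {"gene": r.gene, "cell_type": r.cell_type, "rho": r.rho,
                         "p": r.p, "p_adj": r.p_adj}
                        for r in recs
                    ]
                pd.DataFrame(rows).to_csv(out / "gene_cell_correlations.tsv", sep="\t", index=False)
                contrast = immune.compare_groups(fr, merged.group.reindex(fr.sample_ids))
                contrast.to_csv(out / "fraction_group_contrast.tsv", sep="\t", index=False)
                manifest["stages"]["immune"] = {"samples": len(fr.sample_ids), "pairs": len(rows)}
                log.info("immune: %d gene-cell pairs on %d samples", len(rows), len(fr.sample_ids))

        if cfg.enabled("cluster"):
            if merged is None:
                raise DataError("cluster stage needs the preprocess stage")
            genes = key_genes or _candidate_genes(out, merged)
            cases = merged.cases()
            res = clustering.consensus_cluster(
                cases.values[genes], k_range=cfg.k_range, H=cfg.consensus_h,
                p_item=cfg.p_item, seed=cfg.seed,
            )
            labels = res.labels
            labels.rename("cluster").to_csv(out / "cluster_labels.tsv", sep="\t", index_label="sample_id")
            pd.DataFrame(
                {"k": list(res.area), "area": list(res.area.values()),
                 "delta_area": [res.delta_area[k] for k in res.area],
                 "pac": [res.pac[k] for k in res.area]}
            ).to_csv(out / "consensus_selection.tsv", sep="\t", index=False)
            np.savetxt(out / f"consensus_k{res.chosen_k}.tsv", res.consensus[res.chosen_k], delimiter="\t")
            if res.chosen_k == 2:
                contrast = clustering.subcluster_contrast(cases.values, labels, genes)
                contrast.to_csv(out / "subcluster_contrast.tsv", sep="\t", index=False)
            manifest["stages"]["cluster"] = {
                "chosen_k": res.chosen_k,
                "cluster_sizes": labels.value_counts().sort_index().tolist(),
            }
            log.info("cluster: chose k=%d, sizes %s", res.chosen_k,
                     labels.value_counts().sort_index().tolist())

        if cfg.enabled("cerna"):
            if merged is None and cfg.cerna_expression is None:
                raise DataError("cerna stage needs expression (preprocess stage or cerna_expression)")
            mt = io.read_interactions(cfg.mrna_mirna)
            lt = io.read_interactions(cfg.lncrna_mirna)
            if cfg.cerna_expression:
                expr = pd.read_csv(cfg.cerna_expression, sep="\t", index_col=0).T
            else:
                expr = merged.values
            genes = key_genes or sorted(set(mt.targets("mRNA")))
            cand, G = build_cerna_network(
                mt, lt, expr, genes,
                alpha_hyper=cfg.hyper_alpha, pcc_min=cfg.pcc_min, alpha_pcc=cfg.pcc_alpha,
            )
            pd.DataFrame([dataclasses.asdict(c) for c in cand]).to_csv(
                out / "cerna_candidates.tsv", sep="\t", index=False
            )
            hubs = rank_hubs(G)
            for i, (node, _, _) in enumerate(hubs, start=1):
                G.nodes[node]["hub_rank"] = i
            io.write_network(G, out / "cerna_network.graphml",
                             out / "cerna_nodes.tsv", out / "cerna_edges.tsv")
            pd.DataFrame(hubs, columns=["lncrna", "degree", "betweenness"]).to_csv(
                out / "cerna_hubs.tsv", sep="\t", index=False
            )
            manifest["stages"]["cerna"] = {
                "candidates": len(cand),
                "retained": sum(c.retained for c in cand),
                "nodes": len(G),
                "hub": hubs[0][0] if hubs else None,
            }
            log.info("cerna: %d candidates, %d retained, %d network nodes",
                     len(cand), sum(c.retained for c in cand), len(G))

        if cfg.enabled("roc"):
            if merged is None:
                raise DataError("roc stage needs the preprocess stage")
            genes = key_genes or _candidate_genes(out, merged)
            summary = {}
            y = merged.case_mask().astype(int)
            for g in genes:
                summary[g] = diagnostics.roc_auc(merged.values[g], y, name=g).auc
            combined = diagnostics.combined_panel_score(merged.values, y, merged.values, genes)
            summary["combined"] = diagnostics.roc_auc(combined, y, name="combined").auc
            if cfg.validation_expression:
                val = io.read_expression(
                    cfg.validation_expression["values"], cfg.validation_expression["metadata"]
                )
                yv = val.case_mask().astype(int)
                for g in genes:
                    if g in val.values.columns:
                        summary[f"validation:{g}"] = diagnostics.roc_auc(val.values[g], yv, name=g).auc
                vg = [g for g in genes if g in val.values.columns]
                if vg:
                    cv = diagnostics.combined_panel_score(val.values, yv, val.values, vg)
                    summary["validation:combined"] = diagnostics.roc_auc(cv, yv).auc
            (out / "roc_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
            manifest["stages"]["roc"] = {"models": len(summary)}
            log.info("roc: %d models scored", len(summary))
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _candidate_genes(out: Path, merged: ExpressionMatrix) -> list[str]:
    """Panel-intersected DE genes if the preprocess stage wrote them, else all genes."""
    path = out / "panel_intersection.txt"
    if path.exists():
        genes = [g for g in path.read_text().splitlines() if g]
        if genes:
            return [g for g in genes if g in merged.values.columns]
    return merged.gene_ids
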