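"""End-to-end orchestration: scan -> co-pathway -> structural screen ->
co-expression -> network -> traits -> hubs/regulators/enrichment.

The validation funnel applies the biological criteria in order of increasing
data cost: genomic geometry (the scan), pathway annotation (co-pathway),
gene-family structure (the non-homology screen), and finally expression
(co-expression against the metabolic-pair null).  The reported funnel counts
(candidates scanned, passing co-pathway, passing co-expression) are monotone
non-increasing by construction.

When the inputs come from the synthetic generator, the ground-truth ledger
can be supplied to score recovery: cluster precision/recall, module adjusted
Rand index, and planted-hub recall.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster_scan import (CandidateCluster, annotate_features,
                           clusters_to_frame, read_external_candidates,
                           scan_candidates)
from .coexpr import (build_pcc_null, coexpr_report, filter_clusters_coexpression,
                     pair_report)
from .copathway import copathway_report, filter_clusters_copathway
from .hubs import (hub_records_to_frame, regulator_cluster_matrix,
                   score_hub_records, select_hubs, enrich_terms)
from .io_core import (ExpressionMatrix, GeneTable, config_hash, read_expression,
                      read_gene_table, read_pathway_table, write_report)
from .network import (ModuleSet, NetworkConfig, TraitSet, adjacency,
                      build_bgc_traits, build_modules, module_trait_correlation)

logger = logging.getLogger("clustermod.pipeline")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "inputs": {
        "genes": None, "expression": None, "samples": None, "pathways": None,
        "external_candidates": None, "ledger": None, "regulators": [],
    },
    "scan": {"max_gap": 20000, "min_genes": 3, "max_genes": 10,
             "max_intervening": 3},
    "copathway": {"per_pathway": True},
    "coexpr": {"percentile": 95.0, "min_fraction": 0.5,
               "max_pairs": 2_000_000, "require_p": True},
    "network": {"power": 6, "network_type": "unsigned",
                "merge_cut_height": 0.25, "min_module_size": 30,
                "cut_height": "auto", "max_block_size": 8000,
                "scale_free_fit_target": 0.8},
    "traits": {"p_max": 0.05, "r2_min": 0.5},
    "hubs": {"mm_min": 0.8, "gs_min": 0.2, "top_k": 30, "trait": None},
    "enrich": {"p_max": 1e-4, "fdr_max": 0.05},
}


class PipelineError(RuntimeError):
    """A hard error in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def load_config(source) -> dict:
    """Load and normalize a pipeline configuration (YAML/JSON path or mapping)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    elif isinstance(source, Mapping):
        user = dict(source)
    else:
        raise TypeError("config must be a path or a mapping")
    cfg = _deep_merge(DEFAULT_CONFIG, user)
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return cfg


def _deep_merge(base: Mapping, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], Mapping) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def _stage(name):
    """Re-raise stage failures as PipelineError naming the stage."""
    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False
    return _ctx()


def run_pipeline(config, out_dir, *, scenario=None) -> dict:
    """Execute the full analysis and write all stage artifacts.

    *config* is a path or mapping (see :data:`DEFAULT_CONFIG`); *scenario*
    optionally supplies in-memory inputs from the synthetic generator instead
    of files.  Returns the run summary (also written to summary.json).
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    # --- inputs -----------------------------------------------------------
    with _stage("inputs"):
        if scenario is not None:
            genes = scenario.gene_table
            pathways = scenario.pathway_table
            ledger = scenario.ledger
        else:
            if not cfg["inputs"]["genes"]:
                raise ValueError("inputs.genes is required")
            dialect = "gff3" if str(cfg["inputs"]["genes"]).endswith((".gff", ".gff3")) else "tsv"
            genes = read_gene_table(cfg["inputs"]["genes"], dialect=dialect)
            pathways = read_pathway_table(cfg["inputs"]["pathways"]) \
                if cfg["inputs"]["pathways"] else pd.DataFrame(
                    columns=["gene_id", "pathway_id", "reaction_id"])
            ledger = None
            if cfg["inputs"]["ledger"]:
                ledger = json.loads(Path(cfg["inputs"]["ledger"]).read_text())

    # --- scan -------------------------------------------------------------
    with _stage("scan"):
        if scenario is None and cfg["inputs"]["external_candidates"]:
            candidates = read_external_candidates(
                cfg["inputs"]["external_candidates"], genes)
        else:
            candidates = scan_candidates(genes, **cfg["scan"])
            annotate_features(candidates, genes)
        write_report(candidates, out / "candidates.tsv")

    # --- co-pathway -------------------------------------------------------
    with _stage("copathway"):
        copath_pass, copath_ev = filter_clusters_copathway(
            candidates, pathways, per_pathway=cfg["copathway"]["per_pathway"])
        write_report(copathway_report(copath_ev), out / "copathway_report.tsv")

    # --- structural non-homology screen ------------------------------------
    with _stage("structural"):
        structural_pass = [c for c in copath_pass if c.nonhomologous]

    # --- co-expression ------------------------------------------------------
    with _stage("coexpr"):
        if scenario is not None:
            expr = scenario.expression
        else:
            if not cfg["inputs"]["expression"]:
                raise ValueError("inputs.expression is required")
            expr = read_expression(cfg["inputs"]["expression"],
                                   cfg["inputs"]["samples"] or None)
        expr = expr.imputed()
        metabolic = sorted(set(pathways["gene_id"]))
        null = build_pcc_null(expr, metabolic,
                              percentile=cfg["coexpr"]["percentile"],
                              max_pairs=cfg["coexpr"]["max_pairs"], seed=seed)
        validated, coexpr_ev = filter_clusters_coexpression(
            structural_pass, expr, null,
            min_fraction=cfg["coexpr"]["min_fraction"],
            require_p=cfg["coexpr"]["require_p"])
        write_report(coexpr_report(coexpr_ev), out / "coexpr_report.tsv")
        write_report(pair_report(coexpr_ev), out / "coexpr_pairs.tsv")
        write_report(clusters_to_frame(validated), out / "validated_clusters.tsv")

    # --- network ------------------------------------------------------------
    with _stage("network"):
        net_cfg = NetworkConfig(**cfg["network"])
        modules, fit_table = build_modules(expr, net_cfg)
        write_report(modules, out / "modules.tsv")
        eig = pd.DataFrame({l: modules.eigengenes[l] for l in modules.labels})
        eig.index.name = "sample_id"
        write_report(eig.reset_index(), out / "eigengenes.tsv")
        write_report(fit_table, out / "soft_threshold.tsv")

    # --- traits -------------------------------------------------------------
    with _stage("traits"):
        traits = build_bgc_traits(validated, expr)
        if len(traits) and modules.labels:
            mt = module_trait_correlation(modules, traits,
                                          p_max=cfg["traits"]["p_max"],
                                          r2_min=cfg["traits"]["r2_min"])
            write_report(mt, out / "module_trait.tsv")
            n_significant = int(mt.significant.to_numpy().sum())
        else:
            mt = None
            n_significant = 0

    # --- hubs ---------------------------------------------------------------
    with _stage("hubs"):
        hub_lists = []
        if modules.labels and len(traits):
            adj = adjacency(expr, int(modules.info.get("power", 6)),
                            net_cfg.network_type)
            records = score_hub_records(expr, modules, adj, traits,
                                        trait=cfg["hubs"]["trait"])
            hub_lists = select_hubs(records, mm_min=cfg["hubs"]["mm_min"],
                                    gs_min=cfg["hubs"]["gs_min"],
                                    top_k=cfg["hubs"]["top_k"])
            write_report(records, out / "hub_scores.tsv")
            write_report(hub_records_to_frame(hub_lists), out / "hubs.tsv")

    # --- regulators ---------------------------------------------------------
    with _stage("regulators"):
        regulator_ids = list(cfg["inputs"]["regulators"] or [])
        if scenario is not None and not regulator_ids:
            regulator_ids = [r["gene_id"] for r in scenario.ledger.get("regulators", [])]
        reg_flags = {}
        if regulator_ids and validated:
            frames = []
            for c in validated:
                r_df, p_df, flags = regulator_cluster_matrix(
                    expr, regulator_ids, c, null=null)
                long = r_df.stack().rename("r").to_frame()
                long["p"] = p_df.stack()
                long.index.names = ["regulator", "member"]
                long = long.reset_index()
                long.insert(0, "cluster_id", c.cluster_id)
                frames.append(long)
                reg_flags[c.cluster_id] = {g: bool(flags[g]) for g in flags.index}
            write_report(pd.concat(frames, ignore_index=True),
                         out / "regulator_matrix.tsv")

    # --- enrichment -----------------------------------------------------------
    with _stage("enrich"):
        term_map = {g.gene_id: set(g.enzyme_classes) for g in genes if g.enzyme_classes}
        universe = [g for g in genes.gene_ids if g in expr]
        enrich_frames = []
        for label in modules.labels:
            members = [g for g in modules.members(label) if g in expr]
            table = enrich_terms(members, universe, term_map,
                                 p_max=cfg["enrich"]["p_max"],
                                 fdr_max=cfg["enrich"]["fdr_max"])
            if len(table):
                table.insert(0, "module_label", label)
                enrich_frames.append(table)
        enrichment = (pd.concat(enrich_frames, ignore_index=True)
                      if enrich_frames else pd.DataFrame(
                          columns=["module_label", "term_id", "n_module",
                                   "n_universe", "n_term_universe",
                                   "n_term_module", "p", "fdr"]))
        write_report(enrichment, out / "enrichment.tsv")

    # --- summary ---------------------------------------------------------------
    with _stage("summary"):
        sizes = modules.sizes()
        module_sizes = [sizes[l] for l in modules.labels]
        summary = {
            "version": __version__,
            "seed": seed,
            "config_hash": config_hash(cfg),
            "funnel": {
                "candidates_scanned": len(candidates),
                "copathway_pass": len(copath_pass),
                "coexpression_pass": len(validated),
            },
            "pcc_null_threshold": null.threshold,
            "n_modules": len(modules.labels),
            "module_size_range": ([min(module_sizes), max(module_sizes)]
                                  if module_sizes else [0, 0]),
            "significant_module_trait_cells": n_significant,
            "hub_counts": _hub_counts(hub_lists),
            "regulator_flags": reg_flags,
            "ledger_scores": (score_against_ledger(validated, modules,
                                                   hub_lists, ledger)
                              if ledger else None),
        }
        assert (summary["funnel"]["candidates_scanned"]
                >= summary["funnel"]["copathway_pass"]
                >= summary["funnel"]["coexpression_pass"]), "funnel not monotone"
        write_report(summary, out / "summary.json", format="json")
    return summary


def _hub_counts(hub_lists) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in hub_lists:
        counts[rec.module_label] = counts.get(rec.module_label, 0) + 1
    return dict(sorted(counts.items()))


# ---------------------------------------------------------------------------
# Ledger scoring
# ---------------------------------------------------------------------------

def score_against_ledger(validated: list[CandidateCluster], modules: ModuleSet,
                         hub_lists, ledger: Mapping) -> dict:
    """Score recovery against the synthetic ground truth.

    A planted true cluster counts as recovered when >= 80% of its members
    fall inside one validated candidate; a validated candidate is a true
    positive when it recovers some planted true cluster.  Module recovery is
    the adjusted Rand index between the assignment and the planted module
    membership over planted module genes.  Hub recall is the fraction of
    planted hubs present in the selected hub lists.
    """
    truths = [c for c in ledger.get("clusters", []) if c.get("kind", "true") == "true"]
    recovered = set()
    tp_candidates = set()
    for t in truths:
        members = set(t["gene_ids"])
        for v in validated:
            overlap = len(members & set(v.gene_ids))
            if overlap >= 0.8 * len(members):
                recovered.add(t["cluster_id"])
                tp_candidates.add(v.cluster_id)
    recall = len(recovered) / len(truths) if truths else None
    precision = (len(tp_candidates) / len(validated)) if validated else (
        None if not truths else 0.0)

    ari = None
    planted_modules = ledger.get("modules", [])
    if planted_modules:
        from sklearn.metrics import adjusted_rand_score

        genes, truth_labels, pred_labels = [], [], []
        for m in planted_modules:
            for g in m["gene_ids"]:
                genes.append(g)
                truth_labels.append(m["label"])
                pred_labels.append(modules.assignment.get(g, "missing"))
        ari = float(adjusted_rand_score(truth_labels, pred_labels))

    hub_recall = None
    planted_hubs = {h for m in planted_modules for h in m.get("hub_ids", [])}
    if planted_hubs:
        selected = {r.gene_id for r in hub_lists}
        hub_recall = len(planted_hubs & selected) / len(planted_hubs)

    return {"cluster_precision": precision, "cluster_recall": recall,
            "module_ari": ari, "hub_recall": hub_recall}
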