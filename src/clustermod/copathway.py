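"""Co-pathway validation of candidate clusters.

A candidate passes when, for at least one metabolic pathway, (a) two or more
of its member genes are annotated with that same pathway identifier and (b)
the members sharing it are classified into at least two distinct reactions.
Both criteria are evaluated per shared pathway: pooling reactions across
unrelated pathways would pass clusters whose members have no pathway in
common.  A cluster-wide reading of criterion (b) is available via
``per_pathway=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cluster_scan import CandidateCluster


@dataclass
class CopathwayEvidence:
    cluster_id: str
    #: pathway_id -> (n member genes sharing it, distinct reactions among them)
    qualifying_pathways: dict = field(default_factory=dict)
    passed: bool = False


def copathway_pass(cluster: CandidateCluster, annot: pd.DataFrame,
                   per_pathway: bool = True) -> CopathwayEvidence:
    """Evaluate the two co-pathway criteria for one candidate cluster.

    *annot* is the pathway annotation table (gene_id, pathway_id,
    reaction_id).  Members without annotation are permitted; a fully
    unannotated cluster fails with empty evidence.  Genes carrying multiple
    reactions in the same pathway contribute all of them to the distinct
    count.
    """
    members = set(cluster.gene_ids)
    sub = annot[annot["gene_id"].isin(members)]
    evidence: dict[str, tuple[int, int]] = {}
    for pwy, grp in sub.groupby("pathway_id", sort=True):
        evidence[pwy] = (grp["gene_id"].nunique(), grp["reaction_id"].nunique())
    if per_pathway:
        passed = any(n_genes >= 2 and n_rxn >= 2
                     for n_genes, n_rxn in evidence.values())
    else:
        shared = any(n_genes >= 2 for n_genes, _ in evidence.values())
        passed = shared and sub["reaction_id"].nunique() >= 2
    return CopathwayEvidence(cluster.cluster_id, evidence, passed)


def filter_clusters_copathway(clusters: list[CandidateCluster],
                              annot: pd.DataFrame, per_pathway: bool = True,
                              ) -> tuple[list[CandidateCluster], list[CopathwayEvidence]]:
    """Apply the co-pathway criteria to every candidate.

    Returns the passing clusters (verdicts recorded in place) and the full
    evidence list for reporting — one entry per input cluster.
    """
    passing, report = [], []
    for c in clusters:
        ev = copathway_pass(c, annot, per_pathway=per_pathway)
        best = max(ev.qualifying_pathways.items(),
                   key=lambda kv: (kv[1][0] >= 2 and kv[1][1] >= 2, kv[1]),
                   default=(None, (0, 0)))
        c.set_verdict("copathway", ev.passed,
                      f"pathway={best[0]};genes={best[1][0]};reactions={best[1][1]}"
                      if best[0] else "no annotated members")
        report.append(ev)
        if ev.passed:
            passing.append(c)
    return passing, report


def copathway_report(report: list[CopathwayEvidence]) -> pd.DataFrame:
    """Long-format report: one row per (cluster, pathway) pair plus verdict."""
    rows = []
    for ev in report:
        if not ev.qualifying_pathways:
            rows.append({"cluster_id": ev.cluster_id, "pathway_id": "",
                         "n_genes": 0, "n_reactions": 0, "pass": ev.passed})
        for pwy in sorted(ev.qualifying_pathways):
            n_genes, n_rxn = ev.qualifying_pathways[pwy]
            rows.append({"cluster_id": ev.cluster_id, "pathway_id": pwy,
                         "n_genes": n_genes, "n_reactions": n_rxn,
                         "pass": ev.passed})
    return pd.DataFrame(rows, columns=["cluster_id", "pathway_id", "n_genes",
                                       "n_reactions", "pass"])
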