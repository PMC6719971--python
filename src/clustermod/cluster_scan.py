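"""Candidate biosynthetic gene cluster identification.

Plant BGCs are runs of physically adjacent, non-homologous genes encoding
different enzymes of one pathway; characterized clusters typically hold 3-10
genes and almost always a cytochrome P450.  The scanner below is a
transparent gap-based stand-in for dedicated genome-mining tools: maximal
runs of enzyme-annotated genes where consecutive enzyme genes lie within
``max_gap`` bp of each other and at most ``max_intervening`` non-enzyme genes
sit between them.  Externally predicted candidate lists (rendered as TSV) can
be ingested instead, and receive the same structural-feature annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io_core import GeneModel, GeneTable

logger = logging.getLogger("clustermod.scan")

#: Case-insensitive substrings identifying a cytochrome P450 enzyme class.
P450_SYNONYMS = ("cyp", "p450", "cytochrome p450")

DEFAULT_MAX_GAP = 20_000
DEFAULT_MIN_GENES = 3
DEFAULT_MAX_GENES = 10
DEFAULT_MAX_INTERVENING = 3


@dataclass
class CandidateCluster:
    """An ordered run of genes with structural features and filter verdicts.

    ``verdicts`` maps filter name -> (status, evidence) where status is one of
    ``pass``/``fail``/``not_run``.
    """

    cluster_id: str
    chrom: str
    gene_ids: list[str]
    span: tuple[int, int]
    source: str = "scanned"
    n_genes: int = 0
    enzyme_class_count: int = 0
    has_p450: bool = False
    nonhomologous: bool = False
    verdicts: dict = field(default_factory=dict)

    def __post_init__(self):
        self.n_genes = len(self.gene_ids)

    def set_verdict(self, name: str, passed: bool, evidence: str = "") -> None:
        self.verdicts[name] = ("pass" if passed else "fail", evidence)

    def verdict(self, name: str) -> str:
        return self.verdicts.get(name, ("not_run", ""))[0]


def _is_p450(enzyme_class: str, synonyms=P450_SYNONYMS) -> bool:
    lowered = enzyme_class.lower()
    return any(s in lowered for s in synonyms)


def _check_sorted(genes: list[GeneModel]) -> None:
    keys = [(g.chrom, g.start) for g in genes]
    if keys != sorted(keys):
        raise ValueError("gene table must be position-sorted by (chrom, start); "
                         "refusing to re-sort externally supplied structures")


def scan_candidates(genes: GeneTable, max_gap: int = DEFAULT_MAX_GAP,
                    min_genes: int = DEFAULT_MIN_GENES,
                    max_genes: int = DEFAULT_MAX_GENES,
                    max_intervening: int = DEFAULT_MAX_INTERVENING,
                    ) -> list[CandidateCluster]:
    """Identify maximal runs of enzyme-annotated genes as candidate clusters.

    Two consecutive enzyme genes extend a run when the intergenic distance
    (next start minus previous end) is <= *max_gap* and at most
    *max_intervening* non-enzyme genes lie between them.  Runs whose enzyme
    gene count falls in [*min_genes*, *max_genes*] are emitted; strand is
    ignored.  Non-enzyme genes are never cluster members.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be > 0")
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")
    gene_list = list(genes)
    _check_sorted(gene_list)

    candidates: list[CandidateCluster] = []
    run: list[GeneModel] = []
    intervening = 0
    prev_chrom = None

    def close_run():
        nonlocal run
        if min_genes <= len(run) <= max_genes:
            candidates.append(_make_cluster(run, len(candidates) + 1))
        elif len(run) > max_genes:
            logger.info("dropping run of %d enzyme genes on %s (> max_genes=%d)",
                        len(run), run[0].chrom, max_genes)
        run = []

    for g in gene_list:
        if g.chrom != prev_chrom:
            close_run()
            intervening = 0
            prev_chrom = g.chrom
        if not g.is_enzyme:
            if run:
                intervening += 1
                if intervening > max_intervening:
                    close_run()
                    intervening = 0
            continue
        if run:
            gap = g.start - run[-1].end
            if gap > max_gap or intervening > max_intervening:
                close_run()
        run.append(g)
        intervening = 0
    close_run()
    return candidates


def _make_cluster(run: list[GeneModel], index: int) -> CandidateCluster:
    return CandidateCluster(
        cluster_id=f"C{index:03d}",
        chrom=run[0].chrom,
        gene_ids=[g.gene_id for g in run],
        span=(min(g.start for g in run), max(g.end for g in run)),
        source="scanned",
    )


def structural_features(cluster: CandidateCluster, genes: GeneTable,
                        p450_synonyms=P450_SYNONYMS) -> CandidateCluster:
    """Fill has_p450, enzyme_class_count and the non-homology flag in place.

    ``nonhomologous`` is true unless every member shares one protein-family
    label — the homology proxy standing in for a pairwise alignment test.
    P450 matching is case-insensitive against a configurable synonym list.
    """
    members = [genes[g] for g in cluster.gene_ids]
    classes = set()
    for m in members:
        classes.update(m.enzyme_classes)
    cluster.enzyme_class_count = len(classes)
    cluster.has_p450 = any(_is_p450(c, p450_synonyms) for c in classes)
    shared = None
    all_share_one = True
    family_sets = [m.family_ids for m in members]
    common = set.intersection(*(set(f) for f in family_sets)) if family_sets else set()
    all_share_one = bool(common) and len(members) > 1
    cluster.nonhomologous = not all_share_one
    cluster.set_verdict(
        "structural", cluster.nonhomologous,
        f"enzyme_classes={cluster.enzyme_class_count};p450={cluster.has_p450};"
        f"shared_family={','.join(sorted(common)) if common else 'none'}")
    return cluster


def annotate_features(clusters: list[CandidateCluster], genes: GeneTable,
                      p450_synonyms=P450_SYNONYMS) -> list[CandidateCluster]:
    for c in clusters:
        structural_features(c, genes, p450_synonyms)
    return clusters


def read_external_candidates(path, genes: GeneTable) -> list[CandidateCluster]:
    """Read an externally predicted candidate list (TSV: cluster_id, gene_id).

    Members listed out of positional order are re-sorted by start with a
    warning; a member absent from the gene table is a hard error naming both
    the cluster and the gene.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"cluster_id", "gene_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    clusters = []
    for cid, grp in df.groupby("cluster_id", sort=True):
        ids = list(grp["gene_id"])
        for gid in ids:
            if gid not in genes:
                raise ValueError(
                    f"{path}: cluster {cid} references unknown gene {gid}")
        ordered = sorted(ids, key=lambda g: (genes[g].chrom, genes[g].start))
        if ordered != ids:
            logger.warning("cluster %s: members re-sorted by genomic position", cid)
        members = [genes[g] for g in ordered]
        chroms = {m.chrom for m in members}
        if len(chroms) > 1:
            raise ValueError(f"{path}: cluster {cid} spans chromosomes {sorted(chroms)}")
        clusters.append(CandidateCluster(
            cluster_id=str(cid), chrom=members[0].chrom, gene_ids=ordered,
            span=(min(m.start for m in members), max(m.end for m in members)),
            source="external",
        ))
    annotate_features(clusters, genes)
    return clusters


def clusters_to_frame(clusters: list[CandidateCluster]) -> pd.DataFrame:
    """Deterministic tabular rendering for reports."""
    rows = [{
        "cluster_id": c.cluster_id,
        "chrom": c.chrom,
        "start": c.span[0],
        "end": c.span[1],
        "n_genes": c.n_genes,
        "gene_ids": ";".join(c.gene_ids),
        "enzyme_class_count": c.enzyme_class_count,
        "has_p450": c.has_p450,
        "nonhomologous": c.nonhomologous,
        "source": c.source,
        "verdict_structural": c.verdict("structural"),
        "verdict_copathway": c.verdict("copathway"),
        "verdict_coexpression": c.verdict("coexpression"),
    } for c in clusters]
    return pd.DataFrame(rows, columns=[
        "cluster_id", "chrom", "start", "end", "n_genes", "gene_ids",
        "enzyme_class_count", "has_p450", "nonhomologous", "source",
        "verdict_structural", "verdict_copathway", "verdict_coexpression"])
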