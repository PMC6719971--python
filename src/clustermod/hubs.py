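"""Hub-gene scoring, regulator co-expression matrices, and term enrichment.

Module membership (MM) is the absolute Pearson correlation of a gene's
profile with its module eigengene; gene significance (GS) the absolute
correlation with a trait vector; intramodular connectivity (k_within) the
sum of a gene's adjacency weights to same-module partners.  Hubs are the
genes passing MM > 0.8 and GS > 0.2 with the highest k_within, truncated to
the top 30 per module by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .cluster_scan import CandidateCluster
from .coexpr import PccNull, _pvalue_from_r, _standardized_rows, pcc
from .io_core import ExpressionMatrix
from .network import ModuleSet, TraitSet, UNASSIGNED

logger = logging.getLogger("clustermod.hubs")

DEFAULT_MM_MIN = 0.8
DEFAULT_GS_MIN = 0.2
DEFAULT_TOP_K = 30


@dataclass
class HubRecord:
    gene_id: str
    module_label: str
    mm: float                 # |cor(gene, ME)|, in [0, 1]
    gs: float                 # |cor(gene, trait)| under the trait policy
    k_within: float           # sum of intramodular adjacency, >= 0
    gs_trait: str = ""        # trait id realizing GS (policy = max)
    is_hub: bool = False
    rank: int = 0             # k_within rank within module (1 = highest)


def module_membership(expr: ExpressionMatrix, modules: ModuleSet, gene_id: str,
                      module_label: str | None = None) -> float:
    """MM = |pcc(gene profile, module eigengene)|.

    For an unassigned gene a target *module_label* must be named.
    """
    if module_label is None:
        module_label = modules.assignment.get(gene_id)
        if module_label in (None, UNASSIGNED):
            raise ValueError(
                f"gene {gene_id} is unassigned; name a module_label explicitly")
    me = modules.eigengenes[module_label]
    r, _ = pcc(expr.row(gene_id), me.to_numpy())
    return abs(r)


def gene_significance(expr: ExpressionMatrix, trait: pd.Series, gene_id: str) -> float:
    """GS = |pcc(gene profile, trait vector)|."""
    tv = np.asarray(trait, float)
    if np.std(tv) == 0:
        raise ValueError("zero-variance trait")
    r, _ = pcc(expr.row(gene_id), tv)
    return abs(r)


def intramodular_connectivity(adj: pd.DataFrame, modules: ModuleSet,
                              gene_id: str) -> float:
    """k_within = sum of adjacency weights to same-module genes (no diagonal)."""
    label = modules.assignment.get(gene_id)
    if label in (None, UNASSIGNED):
        raise ValueError(f"gene {gene_id} is not assigned to a module")
    partners = [g for g in modules.members(label) if g != gene_id and g in adj.index]
    if not partners:
        return 0.0
    return float(adj.loc[gene_id, partners].sum())


def score_hub_records(expr: ExpressionMatrix, modules: ModuleSet,
                      adj: pd.DataFrame, traits: TraitSet,
                      trait: str | None = None) -> list[HubRecord]:
    """Score MM, GS and k_within for every assigned gene (vectorized).

    GS trait policy: the maximum GS across the trait set (the default, since
    hubs are evaluated against the cluster traits collectively), or a single
    named *trait*.
    """
    if trait is not None and trait not in traits.traits:
        raise ValueError(f"unknown trait: {trait}")
    trait_ids = [trait] if trait else sorted(traits.traits)
    T = np.vstack([np.asarray(traits.traits[t], float) for t in trait_ids]) \
        if trait_ids else np.empty((0, expr.n_samples))
    Tz = _standardized_rows(T) if len(trait_ids) else T

    records = []
    for label in modules.labels:
        members = [g for g in modules.members(label) if g in expr]
        if not members:
            continue
        X = expr.values.loc[members].to_numpy()
        Xz = _standardized_rows(X)
        me = modules.eigengenes[label].to_numpy()
        mez = (me - me.mean()) / (np.linalg.norm(me - me.mean()))
        mm = np.abs(np.nan_to_num(Xz @ mez))
        if len(trait_ids):
            gs_all = np.abs(np.nan_to_num(Xz @ Tz.T))  # members x traits
            gs_idx = gs_all.argmax(axis=1)
            gs = gs_all.max(axis=1)
        else:
            gs = np.zeros(len(members))
            gs_idx = np.zeros(len(members), dtype=int)
        in_adj = [g for g in members if g in adj.index]
        sub = adj.loc[in_adj, in_adj].to_numpy(copy=True)
        np.fill_diagonal(sub, 0.0)
        kw = dict(zip(in_adj, sub.sum(axis=1)))
        for i, g in enumerate(members):
            records.append(HubRecord(
                gene_id=g, module_label=label,
                mm=float(mm[i]), gs=float(gs[i]),
                k_within=float(kw.get(g, 0.0)),
                gs_trait=trait_ids[gs_idx[i]] if len(trait_ids) else "",
            ))
    return records


def select_hubs(records: list[HubRecord], mm_min: float = DEFAULT_MM_MIN,
                gs_min: float = DEFAULT_GS_MIN,
                top_k: int = DEFAULT_TOP_K) -> list[HubRecord]:
    """Select hub genes per module.

    Candidates must satisfy MM > *mm_min* and GS > *gs_min*; they are ranked
    by k_within descending (ties broken by MM descending, then gene id), and
    truncated to *top_k* per module.  The returned list is ordered by module
    label then rank and is invariant to the input record order.
    """
    hubs: list[HubRecord] = []
    by_module: dict[str, list[HubRecord]] = {}
    for rec in records:
        by_module.setdefault(rec.module_label, []).append(rec)
    for label in sorted(by_module):
        qualified = [r for r in by_module[label] if r.mm > mm_min and r.gs > gs_min]
        qualified.sort(key=lambda r: (-r.k_within, -r.mm, r.gene_id))
        if not qualified:
            logger.info("module %s: no genes pass MM > %.2f and GS > %.2f",
                        label, mm_min, gs_min)
        for rank, rec in enumerate(qualified[:top_k], start=1):
            rec.is_hub = True
            rec.rank = rank
            hubs.append(rec)
    return hubs


def hub_records_to_frame(records: list[HubRecord]) -> pd.DataFrame:
    rows = [{
        "gene_id": r.gene_id, "module_label": r.module_label,
        "MM": r.mm, "GS": r.gs, "gs_trait": r.gs_trait,
        "k_within": r.k_within, "is_hub": r.is_hub, "rank": r.rank,
    } for r in sorted(records, key=lambda r: (r.module_label, r.rank or 10 ** 9,
                                              -r.k_within, r.gene_id))]
    return pd.DataFrame(rows, columns=["gene_id", "module_label", "MM", "GS",
                                       "gs_trait", "k_within", "is_hub", "rank"])


# ---------------------------------------------------------------------------
# Regulator-cluster co-expression
# ---------------------------------------------------------------------------

def regulator_cluster_matrix(expr: ExpressionMatrix, regulator_ids,
                             cluster: CandidateCluster,
                             null: PccNull | None = None,
                             flag_fraction: float = 0.5,
                             ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Correlation matrix between candidate regulators and cluster members.

    Returns (r, p, flags): r and p are regulators x members DataFrames; a
    regulator is flagged "highly co-expressed" when at least *flag_fraction*
    of its entries exceed the PCC null threshold (flags are all-False when no
    null is supplied).  Absent gene ids are skipped with a warning; an empty
    regulator set is an error.
    """
    regulators = sorted(set(regulator_ids))
    if not regulators:
        raise ValueError("empty regulator set")
    reg_present = [g for g in regulators if g in expr]
    for g in regulators:
        if g not in expr:
            logger.warning("regulator %s has no expression row; skipped", g)
    members = [g for g in cluster.gene_ids if g in expr]
    for g in cluster.gene_ids:
        if g not in expr:
            logger.warning("cluster member %s has no expression row; skipped", g)
    if not reg_present or not members:
        raise ValueError("no expressed regulators or no expressed cluster members")
    Rz = _standardized_rows(expr.values.loc[reg_present].to_numpy())
    Mz = _standardized_rows(expr.values.loc[members].to_numpy())
    r = np.clip(np.nan_to_num(Rz @ Mz.T), -1.0, 1.0)
    p = _pvalue_from_r(r, expr.n_samples)
    r_df = pd.DataFrame(r, index=reg_present, columns=members)
    p_df = pd.DataFrame(p, index=reg_present, columns=members)
    if null is not None:
        flags = (r_df >= null.threshold).mean(axis=1) >= flag_fraction
    else:
        flags = pd.Series(False, index=reg_present)
    flags.name = "highly_coexpressed"
    return r_df, p_df, flags


# ---------------------------------------------------------------------------
# Term enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRow:
    term_id: str
    n_module: int
    n_universe: int
    n_term_universe: int
    n_term_module: int
    p: float
    fdr: float


def enrich_terms(module_genes, universe_genes, term_map,
                 p_max: float = 1e-4, fdr_max: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of terms in a module.

    *term_map* maps gene_id -> set of term ids over the universe.  For every
    term hitting the module, p is the hypergeometric upper tail of observing
    at least the module count; Benjamini-Hochberg correction runs across the
    tested terms.  Rows with p < *p_max* and fdr < *fdr_max* are returned,
    sorted by p.  The module must be a subset of the universe.
    """
    module = set(module_genes)
    universe = set(universe_genes)
    if not module <= universe:
        raise ValueError("module genes must be a subset of the universe")
    term_universe: dict[str, set] = {}
    for gene, terms in term_map.items():
        if gene not in universe:
            continue
        for t in terms:
            term_universe.setdefault(t, set()).add(gene)
    N, n = len(universe), len(module)
    rows = []
    for term in sorted(term_universe):
        hits = term_universe[term] & module
        if not hits:
            continue
        K, k = len(term_universe[term]), len(hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "n_module": n, "n_universe": N,
                     "n_term_universe": K, "n_term_module": k, "p": p})
    if not rows:
        return pd.DataFrame(columns=["term_id", "n_module", "n_universe",
                                     "n_term_universe", "n_term_module", "p", "fdr"])
    df = pd.DataFrame(rows)
    from statsmodels.stats.multitest import multipletests

    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    kept = df[(df["p"] < p_max) & (df["fdr"] < fdr_max)]
    return kept.sort_values(["p", "term_id"]).reset_index(drop=True)


def hypergeom_tail_exact(k: int, N: int, K: int, n: int) -> float:
    """Exact combinatorial upper tail P(X >= k), X ~ Hypergeometric(N, K, n).

    Reference implementation by direct summation of binomial coefficients;
    used as an independent cross-check of the enrichment p-values.
    """
    denom = comb(N, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        total += comb(K, x) * comb(N - K, n - x)
    return total / denom
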