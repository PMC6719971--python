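"""Co-expression validation of candidate clusters.

A cluster shows a co-expression pattern when a sufficient fraction of its
member gene pairs are correlated above a data-derived threshold: the 95th
percentile of the Pearson correlation distribution over all metabolic gene
pairs (the empirical null), with the pairwise correlations additionally
required to be individually significant (two-sided p < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster_scan import CandidateCluster
from .io_core import ExpressionMatrix

logger = logging.getLogger("clustermod.coexpr")

DEFAULT_PERCENTILE = 95.0
DEFAULT_MIN_FRACTION = 0.5
DEFAULT_MAX_PAIRS = 2_000_000


@dataclass
class PccNull:
    """Empirical Pearson-correlation null over metabolic gene pairs."""

    threshold: float
    percentile: float = DEFAULT_PERCENTILE
    n_pairs_sampled: int = 0
    sampling_seed: Optional[int] = None


@dataclass
class ClusterCoexprEvidence:
    cluster_id: str
    #: (gene_i, gene_j) -> (r, p) over unordered member pairs
    pair_pcc: dict = field(default_factory=dict)
    n_pairs_scored: int = 0
    n_pairs_significant: int = 0      # p < 0.05
    n_pairs_above_threshold: int = 0  # r >= threshold AND p < 0.05
    passed: bool = False
    reason: str = ""


def pcc(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with a two-sided p-value (t transform, n-2 df).

    A zero-variance vector yields (nan, nan) with a warning so the pair can
    be excluded from counts rather than aborting a whole cluster.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("correlation requires at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero-variance vector in pcc; returning NaN")
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _pvalue_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the t transform with n-2 df (vectorized)."""
    r = np.clip(np.asarray(r, float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def _standardized_rows(values: np.ndarray) -> np.ndarray:
    """Rows centered and scaled to unit norm; zero-variance rows become NaN."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return centered / norms


def build_pcc_null(expr: ExpressionMatrix, metabolic_genes,
                   percentile: float = DEFAULT_PERCENTILE,
                   max_pairs: int = DEFAULT_MAX_PAIRS,
                   seed: Optional[int] = None) -> PccNull:
    """Estimate the PCC null from all metabolic gene pairs.

    Computes r over every unordered pair of metabolic genes present in the
    expression matrix, or a seeded uniform subsample of *max_pairs* pairs
    when the full pair count exceeds it.  The threshold is the stated
    percentile of the signed r distribution, using linear interpolation
    between order statistics (nearest-rank differs at small n).
    """
    genes = [g for g in sorted(set(metabolic_genes)) if g in expr]
    if len(genes) < 2:
        raise ValueError(
            f"need >= 2 metabolic genes with expression, got {len(genes)}")
    Z = _standardized_rows(expr.values.loc[genes].to_numpy())
    keep = ~np.isnan(Z).any(axis=1)
    if (~keep).any():
        logger.warning("excluding %d zero-variance metabolic genes from the null",
                       int((~keep).sum()))
        Z = Z[keep]
    m = Z.shape[0]
    if m < 2:
        raise ValueError("fewer than 2 usable metabolic genes (zero variance)")
    total_pairs = m * (m - 1) // 2
    if total_pairs <= max_pairs:
        r_full = Z @ Z.T
        iu = np.triu_indices(m, k=1)
        r_values = r_full[iu]
        used_seed = None
    else:
        rng = np.random.default_rng(seed)
        flat = rng.choice(total_pairs, size=max_pairs, replace=False)
        i, j = _pair_from_flat_index(flat, m)
        r_values = np.einsum("ij,ij->i", Z[i], Z[j])
        used_seed = seed
    threshold = float(np.percentile(r_values, percentile, method="linear"))
    return PccNull(threshold=threshold, percentile=percentile,
                   n_pairs_sampled=len(r_values), sampling_seed=used_seed)


def _pair_from_flat_index(flat: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Map flat indices 0..C(m,2)-1 to upper-triangle (i, j) pairs, i < j."""
    flat = np.asarray(flat, dtype=np.int64)
    # Row i starts at offset i*m - i*(i+1)/2 - i ... solve via quadratic formula.
    b = 2 * m - 1
    i = np.floor((b - np.sqrt(b * b - 8.0 * flat)) / 2.0).astype(np.int64)
    start = i * (2 * m - i - 1) // 2
    j = flat - start + i + 1
    return i, j


def cluster_coexpression(cluster: CandidateCluster, expr: ExpressionMatrix,
                         null: PccNull,
                         min_fraction: float = DEFAULT_MIN_FRACTION,
                         require_p: bool = True) -> ClusterCoexprEvidence:
    """Score all unordered member pairs and decide the co-expression verdict.

    Pass requires (pairs with r >= null.threshold, and p < 0.05 when
    *require_p*) to make up at least *min_fraction* of the scored pairs.
    Pairs involving a zero-variance gene are excluded from both counts and
    the denominator.  Fewer than two expressed members fails with reason
    "insufficient expression data".
    """
    present = [g for g in cluster.gene_ids if g in expr]
    ev = ClusterCoexprEvidence(cluster.cluster_id)
    if len(present) < 2:
        ev.passed = False
        ev.reason = "insufficient expression data"
        cluster.set_verdict("coexpression", False, ev.reason)
        return ev
    n = expr.n_samples
    Z = _standardized_rows(expr.values.loc[present].to_numpy())
    for a in range(len(present)):
        for b in range(a + 1, len(present)):
            if np.isnan(Z[a]).any() or np.isnan(Z[b]).any():
                ev.pair_pcc[(present[a], present[b])] = (float("nan"), float("nan"))
                continue
            r = float(np.clip(Z[a] @ Z[b], -1.0, 1.0))
            p = float(_pvalue_from_r(np.array([r]), n)[0])
            ev.pair_pcc[(present[a], present[b])] = (r, p)
            ev.n_pairs_scored += 1
            if p < 0.05:
                ev.n_pairs_significant += 1
            if r >= null.threshold and (p < 0.05 or not require_p):
                ev.n_pairs_above_threshold += 1
    if ev.n_pairs_scored == 0:
        ev.passed = False
        ev.reason = "insufficient expression data"
    else:
        fraction = ev.n_pairs_above_threshold / ev.n_pairs_scored
        ev.passed = fraction >= min_fraction
        ev.reason = (f"{ev.n_pairs_above_threshold}/{ev.n_pairs_scored} pairs "
                     f">= threshold {null.threshold:.3f}")
    cluster.set_verdict("coexpression", ev.passed, ev.reason)
    return ev


def filter_clusters_coexpression(clusters: list[CandidateCluster],
                                 expr: ExpressionMatrix, null: PccNull,
                                 min_fraction: float = DEFAULT_MIN_FRACTION,
                                 require_p: bool = True,
                                 ) -> tuple[list[CandidateCluster], list[ClusterCoexprEvidence]]:
    passing, report = [], []
    for c in clusters:
        ev = cluster_coexpression(c, expr, null, min_fraction, require_p)
        report.append(ev)
        if ev.passed:
            passing.append(c)
    return passing, report


def coexpr_report(report: list[ClusterCoexprEvidence]) -> pd.DataFrame:
    rows = [{
        "cluster_id": ev.cluster_id,
        "n_pairs_scored": ev.n_pairs_scored,
        "n_pairs_significant": ev.n_pairs_significant,
        "n_pairs_above_threshold": ev.n_pairs_above_threshold,
        "pass": ev.passed,
        "reason": ev.reason,
    } for ev in report]
    return pd.DataFrame(rows, columns=["cluster_id", "n_pairs_scored",
                                       "n_pairs_significant",
                                       "n_pairs_above_threshold", "pass", "reason"])


def pair_report(report: list[ClusterCoexprEvidence]) -> pd.DataFrame:
    """Per-pair evidence TSV (gene_i, gene_j, r, p) across clusters."""
    rows = []
    for ev in report:
        for (gi, gj), (r, p) in sorted(ev.pair_pcc.items()):
            rows.append({"cluster_id": ev.cluster_id, "gene_i": gi,
                         "gene_j": gj, "r": r, "p": p})
    return pd.DataFrame(rows, columns=["cluster_id", "gene_i", "gene_j", "r", "p"])
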