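"""Weighted co-expression network construction and module detection.

The construction follows the standard weighted gene co-expression network
recipe: a soft-thresholded adjacency built from pairwise Pearson
correlations, smoothed into a topological overlap matrix (TOM), clustered by
average-linkage hierarchical clustering on the TOM dissimilarity 1 - TOM,
cut into modules, summarized by module eigengenes (first principal component
of the standardized module expression), with close modules merged at an
eigengene dissimilarity below ``merge_cut_height`` (default 0.25).  Module
eigengenes are then correlated against trait vectors — here the expression
profiles of validated biosynthetic-cluster member genes — and a
(module, trait) cell is called significant when p < 0.05 and r^2 > 0.5.

The whole stage is deterministic given the input matrix and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .coexpr import _pvalue_from_r, _standardized_rows
from .io_core import ExpressionMatrix

logger = logging.getLogger("clustermod.network")

UNASSIGNED = "unassigned"

DEFAULT_POWERS = tuple(list(range(1, 11)) + [12, 14, 16, 18, 20])


@dataclass
class NetworkConfig:
    power: int | str = 6                 # soft threshold, or "auto" to sweep
    network_type: str = "unsigned"       # or "signed"
    merge_cut_height: float = 0.25
    min_module_size: int = 30
    cut_height: float | str = "auto"
    max_block_size: int = 8000
    scale_free_fit_target: float = 0.8
    #: clusters whose mean internal dissimilarity exceeds this fraction of the
    #: matrix-wide mean dissimilarity are rejected as incoherent
    module_cohesion: float = 0.9

    def __post_init__(self):
        if not (0 < self.merge_cut_height < 1):
            raise ValueError("merge_cut_height must be in (0, 1)")
        if self.network_type not in ("unsigned", "signed"):
            raise ValueError(f"unknown network_type: {self.network_type!r}")
        if isinstance(self.power, str) and self.power != "auto":
            raise ValueError("power must be an integer or 'auto'")
        if isinstance(self.power, int) and not (1 <= self.power <= 20):
            raise ValueError("power must lie in the sweep range [1, 20]")


@dataclass
class ModuleSet:
    """Gene -> module assignment plus per-module eigengene profiles.

    Every expressed gene carries exactly one label; the reserved label
    ``unassigned`` plays the role of the grey (unclustered) set.
    """

    assignment: dict[str, str]
    eigengenes: dict[str, pd.Series] = field(default_factory=dict)
    var_explained: dict[str, float] = field(default_factory=dict)
    info: dict = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        sizes = self.sizes()
        return [l for l in sizes if l != UNASSIGNED]

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for label in self.assignment.values():
            out[label] = out.get(label, 0) + 1
        return dict(sorted(out.items(), key=lambda kv: (kv[0] == UNASSIGNED, -kv[1], kv[0])))

    def members(self, label: str) -> list[str]:
        return [g for g, l in self.assignment.items() if l == label]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene_id": g, "module_label": l}
                for g, l in sorted(self.assignment.items())]
        return pd.DataFrame(rows, columns=["gene_id", "module_label"])


@dataclass
class TraitSet:
    """Named trait vectors aligned to the expression samples."""

    traits: dict[str, pd.Series]
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self):
        return len(self.traits)


@dataclass
class ModuleTraitResult:
    r: pd.DataFrame          # modules x traits
    p: pd.DataFrame
    significant: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for module in self.r.index:
            for trait in self.r.columns:
                rows.append({
                    "module_label": module, "trait_id": trait,
                    "r": self.r.loc[module, trait],
                    "p": self.p.loc[module, trait],
                    "significant": bool(self.significant.loc[module, trait]),
                })
        return pd.DataFrame(rows, columns=["module_label", "trait_id", "r", "p",
                                           "significant"])


# ---------------------------------------------------------------------------
# Adjacency and topological overlap
# ---------------------------------------------------------------------------

def correlation_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Gene-gene Pearson correlations; zero-variance genes dropped with warning."""
    Z = _standardized_rows(expr.values.to_numpy())
    keep = ~np.isnan(Z).any(axis=1)
    if (~keep).any():
        dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
        logger.warning("excluding %d zero-variance genes from the network: %s%s",
                       len(dropped), dropped[:3], "..." if len(dropped) > 3 else "")
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    C = np.clip(Z[keep] @ Z[keep].T, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=genes, columns=genes)


def adjacency(expr: ExpressionMatrix, beta: int,
              network_type: str = "unsigned") -> pd.DataFrame:
    """Soft-thresholded adjacency: |cor|^beta (unsigned) or ((1+cor)/2)^beta."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    C = correlation_matrix(expr)
    return adjacency_from_correlation(C, beta, network_type)


def adjacency_from_correlation(cor: pd.DataFrame, beta: int,
                               network_type: str = "unsigned") -> pd.DataFrame:
    if network_type == "unsigned":
        A = np.abs(cor.to_numpy()) ** beta
    elif network_type == "signed":
        A = ((1.0 + cor.to_numpy()) / 2.0) ** beta
    else:
        raise ValueError(f"unknown network_type: {network_type!r}")
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=cor.index, columns=cor.columns)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with the
    sum over u distinct from i and j and k_i the connectivity excluding the
    diagonal.  TOM_ii = 1; entries lie in [0, 1] for adjacency in [0, 1].
    """
    A = adj.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be a symmetric square matrix")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    n = A.shape[0]
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A  # includes u = i or j terms only via zero diagonal: none
    numerator = shared + A
    denominator = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numerator / denominator
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


# ---------------------------------------------------------------------------
# Soft-threshold selection
# ---------------------------------------------------------------------------

def pick_soft_threshold(expr: ExpressionMatrix,
                        candidate_powers: Sequence[int] = DEFAULT_POWERS,
                        target_fit: float = 0.8,
                        network_type: str = "unsigned",
                        n_bins: int = 10) -> tuple[int, pd.DataFrame]:
    """Sweep soft-threshold powers for approximate scale-free topology.

    For each power the connectivities k_i are binned (log-spaced counts) and
    log10 p(k) regressed on log10 k; the fit index is the regression R^2
    signed negatively when the slope is positive (scale-free topology demands
    a decreasing degree distribution).  Returns the smallest power reaching
    *target_fit*, else the power of maximal fit with a warning.
    """
    if len(expr.gene_ids) < 50:
        logger.warning("scale-free fit is unreliable below ~50 genes (have %d)",
                       len(expr.gene_ids))
    C = correlation_matrix(expr)
    if C.shape[0] < 3:
        raise ValueError("not enough non-constant genes for a network")
    rows = []
    for power in candidate_powers:
        A = adjacency_from_correlation(C, power, network_type).to_numpy()
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        fit, slope = _scale_free_fit(k, n_bins)
        rows.append({"power": power, "fit": fit, "slope": slope,
                     "mean_k": float(k.mean()), "max_k": float(k.max())})
    table = pd.DataFrame(rows)
    ok = table[table["fit"] >= target_fit]
    if len(ok):
        best = int(ok.iloc[0]["power"])
    else:
        best = int(table.loc[table["fit"].idxmax(), "power"])
        logger.warning("no power reached scale-free fit %.2f; using power %d "
                       "(fit %.3f)", target_fit, best, table["fit"].max())
    return best, table


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    if np.allclose(k, k[0]):
        logger.warning("degenerate connectivity distribution (all k equal)")
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        freq = mask.mean()
        if mean_k <= 0 or freq <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(freq))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = np.polyval([slope, intercept], xs)
    ss_res = float(np.sum((np.array(ys) - pred) ** 2))
    ss_tot = float(np.sum((np.array(ys) - np.mean(ys)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return (-r2 if slope > 0 else r2), float(slope)


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def detect_modules(tom: pd.DataFrame, config: NetworkConfig) -> ModuleSet:
    """Cut the average-linkage dendrogram of 1 - TOM into modules.

    With a numeric ``config.cut_height`` a single static cut is made.  With
    the default ``"auto"``, candidate cut heights spanning the dendrogram are
    scanned and the cut maximizing a coverage-weighted mean silhouette over
    the qualifying clusters is kept.  In both cases a cluster qualifies as a
    module only when it has at least ``min_module_size`` genes and its mean
    internal dissimilarity stays below ``module_cohesion`` times the mean
    off-diagonal dissimilarity of the whole matrix — incoherent near-top
    clusters of background genes are rejected rather than reported.  Labels
    are assigned by decreasing module size (M1, M2, ...).
    """
    genes = list(tom.index)
    n = len(genes)
    if n < config.min_module_size:
        logger.warning("fewer genes (%d) than min_module_size (%d); all unassigned",
                       n, config.min_module_size)
        return ModuleSet({g: UNASSIGNED for g in genes}, info={"cut_height": None})
    D = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="average")
    heights = Z[:, 2]
    mean_dissim = float(D[np.triu_indices(n, k=1)].mean())
    cohesion_max = config.module_cohesion * mean_dissim

    if isinstance(config.cut_height, (int, float)):
        candidates = [float(config.cut_height)]
    else:
        candidates = _candidate_heights(heights)

    best = None
    for h in candidates:
        labels = fcluster(Z, t=h, criterion="distance")
        qual = _qualifying_clusters(labels, D, config.min_module_size, cohesion_max)
        score = _cut_score(labels, qual, D)
        if best is None or score > best[0] + 1e-12:
            best = (score, h, labels, qual)
    _, cut_h, labels, qual = best

    assignment = {}
    # Deterministic labels by decreasing size then smallest member gene id.
    order = sorted(qual, key=lambda c: (-int((labels == c).sum()),
                                        min(np.array(genes)[labels == c])))
    rename = {c: f"M{i + 1}" for i, c in enumerate(order)}
    for g, lab in zip(genes, labels):
        assignment[g] = rename.get(lab, UNASSIGNED)
    return ModuleSet(assignment, info={"cut_height": float(cut_h),
                                       "n_candidate_cuts": len(candidates),
                                       "mean_dissim": mean_dissim})


def _candidate_heights(heights: np.ndarray) -> np.ndarray:
    """Candidate cut heights: even coverage of the height range plus the
    quantiles of the merge heights themselves, offset into merge midpoints."""
    h = np.unique(heights)
    if len(h) == 1:
        return np.array([h[0] + 1e-9])
    lo, hi = float(h[0]), float(h[-1])
    grid = np.linspace(lo, hi, 64)
    quant = np.quantile(h, np.linspace(0, 1, 64))
    mid = (h[:-1] + h[1:]) / 2.0
    if len(mid) > 64:
        mid = mid[np.linspace(0, len(mid) - 1, 64).astype(int)]
    return np.unique(np.concatenate([grid, quant, mid, [hi + 1e-9]]))


def _qualifying_clusters(labels: np.ndarray, D: np.ndarray,
                         min_size: int, cohesion_max: float) -> list[int]:
    qual = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < min_size:
            continue
        sub = D[np.ix_(idx, idx)]
        internal = sub[np.triu_indices(len(idx), k=1)].mean()
        if internal <= cohesion_max:
            qual.append(int(c))
    return qual


def _cut_score(labels: np.ndarray, qual: list[int], D: np.ndarray) -> float:
    """Coverage-weighted mean silhouette of genes in qualifying clusters."""
    if not qual:
        return -np.inf
    n = len(labels)
    assigned = np.isin(labels, qual)
    idx = np.flatnonzero(assigned)
    if len(idx) > 2000:  # keep the scan cheap on large blocks
        idx = idx[:: max(1, len(idx) // 2000)]
    sub_labels = labels[idx]
    if len(qual) >= 2:
        from sklearn.metrics import silhouette_samples
        s = silhouette_samples(D[np.ix_(idx, idx)], sub_labels, metric="precomputed")
        mean_s = float(s.mean())
    else:
        inside = np.flatnonzero(np.isin(labels, qual))
        outside = np.flatnonzero(~np.isin(labels, qual))
        sub = D[np.ix_(inside, inside)]
        a = (sub.sum(axis=1)) / max(1, len(inside) - 1)
        if len(outside):
            b = D[np.ix_(inside, outside)].mean(axis=1)
        else:
            b = np.full(len(inside), D.max())
        with np.errstate(invalid="ignore", divide="ignore"):
            s = (b - a) / np.maximum(a, b)
        mean_s = float(np.nan_to_num(s).mean())
    coverage = assigned.mean()
    return coverage * mean_s


# ---------------------------------------------------------------------------
# Eigengenes
# ---------------------------------------------------------------------------

def module_eigengene(expr: ExpressionMatrix, members: Iterable[str],
                     ) -> tuple[pd.Series, float]:
    """First principal component of the standardized module expression.

    Member rows are standardized (zero mean, unit variance); the eigengene is
    the unit-norm first right-singular vector over samples, sign-aligned so
    its correlation with the mean standardized member profile is
    non-negative (ties broken by forcing the first non-zero entry positive).
    ``var_explained`` is the first singular value's share of total variance.
    """
    members = [g for g in members if g in expr]
    if not members:
        raise ValueError("module has no expressed members")
    X = expr.values.loc[members].to_numpy(dtype=float)
    sd = X.std(axis=1)
    usable = sd > 0
    if not usable.any():
        raise ValueError("all member rows are constant; eigengene undefined")
    if (~usable).any():
        logger.warning("dropping %d constant member rows from eigengene",
                       int((~usable).sum()))
        X = X[usable]
    Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    eig = Vt[0]
    var_explained = float(S[0] ** 2 / np.sum(S ** 2))
    mean_profile = Xs.mean(axis=0)
    align = float(np.dot(eig, mean_profile))
    if abs(align) > 1e-10:
        eig = eig * np.sign(align)
    else:  # symmetric (e.g. anti-correlated halves): deterministic orientation
        nz = np.flatnonzero(np.abs(eig) > 1e-12)
        if len(nz) and eig[nz[0]] < 0:
            eig = -eig
    return pd.Series(eig, index=expr.sample_ids), var_explained


def compute_eigengenes(expr: ExpressionMatrix, modules: ModuleSet) -> ModuleSet:
    """Fill eigengenes and var_explained for every module label (not grey)."""
    modules.eigengenes = {}
    modules.var_explained = {}
    for label in modules.labels:
        eig, ve = module_eigengene(expr, modules.members(label))
        modules.eigengenes[label] = eig
        modules.var_explained[label] = ve
    return modules


def merge_close_modules(modules: ModuleSet, expr: ExpressionMatrix,
                        merge_cut_height: float = 0.25) -> ModuleSet:
    """Iteratively merge module pairs with eigengene dissimilarity below cut.

    The closest pair (1 - cor(ME_i, ME_j) < merge_cut_height) is merged and
    eigengenes recomputed before the next pass, so chained merges are
    re-evaluated on the recomputed eigengene.  Labels are reassigned by
    decreasing size afterwards.
    """
    assignment = dict(modules.assignment)
    while True:
        labels = sorted({l for l in assignment.values() if l != UNASSIGNED})
        if len(labels) < 2:
            break
        eigs = {}
        for label in labels:
            members = [g for g, l in assignment.items() if l == label]
            eigs[label], _ = module_eigengene(expr, members)
        best_pair, best_diss = None, None
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                r = float(np.corrcoef(eigs[labels[i]], eigs[labels[j]])[0, 1])
                diss = 1.0 - r
                if best_diss is None or diss < best_diss:
                    best_diss, best_pair = diss, (labels[i], labels[j])
        if best_diss is None or best_diss >= merge_cut_height:
            break
        keep, drop = best_pair
        for g, l in assignment.items():
            if l == drop:
                assignment[g] = keep
    merged = _relabel_by_size(assignment)
    out = ModuleSet(merged, info=dict(modules.info))
    return compute_eigengenes(expr, out)


def _relabel_by_size(assignment: dict[str, str]) -> dict[str, str]:
    sizes: dict[str, int] = {}
    first_gene: dict[str, str] = {}
    for g in sorted(assignment):
        l = assignment[g]
        if l == UNASSIGNED:
            continue
        sizes[l] = sizes.get(l, 0) + 1
        first_gene.setdefault(l, g)
    order = sorted(sizes, key=lambda l: (-sizes[l], first_gene[l]))
    rename = {l: f"M{i + 1}" for i, l in enumerate(order)}
    rename[UNASSIGNED] = UNASSIGNED
    return {g: rename[l] for g, l in assignment.items()}


# ---------------------------------------------------------------------------
# Block-wise orchestration
# ---------------------------------------------------------------------------

def build_modules(expr: ExpressionMatrix, config: NetworkConfig,
                  ) -> tuple[ModuleSet, pd.DataFrame]:
    """Full module stage: power selection, blocks, TOM, detection, merging.

    Matrices larger than ``max_block_size`` genes are split into blocks by
    k-means on standardized expression profiles (deterministic seeding);
    modules are detected per block and reconciled globally by eigengene
    merging.  Returns the final ModuleSet and the soft-threshold fit table
    (single row when the power was fixed).
    """
    expr = expr.imputed()
    if config.power == "auto":
        power, fit_table = pick_soft_threshold(
            expr, target_fit=config.scale_free_fit_target,
            network_type=config.network_type)
    else:
        power, fit_table = int(config.power), pd.DataFrame(
            [{"power": int(config.power), "fit": np.nan, "slope": np.nan,
              "mean_k": np.nan, "max_k": np.nan}])

    gene_ids = expr.gene_ids
    if len(gene_ids) > config.max_block_size:
        blocks = _split_blocks(expr, config.max_block_size)
    else:
        blocks = [gene_ids]

    assignment: dict[str, str] = {}
    for b, block_genes in enumerate(blocks):
        sub = expr.subset(block_genes)
        adj = adjacency(sub, power, config.network_type)
        tom = topological_overlap(adj)
        block_modules = detect_modules(tom, config)
        for g, l in block_modules.assignment.items():
            assignment[g] = UNASSIGNED if l == UNASSIGNED else f"B{b}_{l}"
    pre = ModuleSet(_relabel_by_size(assignment),
                    info={"power": power, "n_blocks": len(blocks)})
    if pre.labels:
        merged = merge_close_modules(pre, expr, config.merge_cut_height)
        merged.info.update(pre.info)
        return merged, fit_table
    return pre, fit_table


def _split_blocks(expr: ExpressionMatrix, max_block_size: int) -> list[list[str]]:
    from sklearn.cluster import KMeans

    n_blocks = -(-len(expr.gene_ids) // max_block_size)
    Z = _standardized_rows(expr.values.to_numpy())
    Z = np.nan_to_num(Z)
    km = KMeans(n_clusters=n_blocks, random_state=0, n_init=10).fit(Z)
    blocks: list[list[str]] = [[] for _ in range(n_blocks)]
    for g, lab in zip(expr.gene_ids, km.labels_):
        blocks[lab].append(g)
    return [b for b in blocks if b]


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def build_bgc_traits(clusters, expr: ExpressionMatrix) -> TraitSet:
    """One trait per validated cluster member gene: its expression profile.

    Trait ids are ``<cluster_id>:<gene_id>``; members without expression are
    skipped with a warning.
    """
    traits: dict[str, pd.Series] = {}
    provenance: dict[str, str] = {}
    for c in clusters:
        n_expressed = 0
        for g in c.gene_ids:
            if g not in expr:
                logger.warning("trait member %s of %s has no expression row; skipped",
                               g, c.cluster_id)
                continue
            tid = f"{c.cluster_id}:{g}"
            traits[tid] = expr.values.loc[g].copy()
            provenance[tid] = c.cluster_id
            n_expressed += 1
        if n_expressed == 0:
            logger.warning("cluster %s contributed no traits", c.cluster_id)
    return TraitSet(traits, provenance)


def module_trait_correlation(modules: ModuleSet, traits: TraitSet,
                             p_max: float = 0.05,
                             r2_min: float = 0.5) -> ModuleTraitResult:
    """Correlate module eigengenes with trait vectors.

    Significance follows the conjunctive rule p < *p_max* AND r^2 > *r2_min*
    (squared Pearson correlation); the sign of r distinguishes positive from
    negative co-regulation and is reported, not gated on.
    """
    if not modules.eigengenes:
        raise ValueError("modules carry no eigengenes; run compute_eigengenes first")
    labels = sorted(modules.eigengenes, key=lambda l: int(l[1:]) if l[1:].isdigit() else 0)
    trait_ids = sorted(traits.traits)
    r = pd.DataFrame(index=labels, columns=trait_ids, dtype=float)
    p = pd.DataFrame(index=labels, columns=trait_ids, dtype=float)
    for label in labels:
        me = modules.eigengenes[label]
        n = len(me)
        for tid in trait_ids:
            tv = traits.traits[tid]
            if list(tv.index) != list(me.index):
                raise ValueError(f"trait {tid} samples not aligned with eigengene")
            if tv.std() == 0:
                raise ValueError(f"trait {tid} has zero variance")
            rr = float(np.corrcoef(me.to_numpy(), tv.to_numpy())[0, 1])
            r.loc[label, tid] = rr
            p.loc[label, tid] = float(_pvalue_from_r(np.array([rr]), n)[0])
    significant = (p < p_max) & (r ** 2 > r2_min)
    return ModuleTraitResult(r, p, significant)
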