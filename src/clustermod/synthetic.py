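"""Synthetic genomes, pathway annotations and expression with planted truth.

The generator emulates a two-species allelopathy co-culture study design: per
species, 16 RNA-seq samples = 4 time points (3 h, 3 d, 7 d, 14 d) x 2
conditions (mono-culture, co-culture) x 2 replicates.  Expression follows a
latent-factor model: each planted co-expression module (and each co-expressed
planted cluster) owns one latent factor over samples; member genes load on
that factor plus independent Gaussian noise, and background genes are pure
noise.  Values are mapped to a non-negative FPKM-like scale by a per-gene
affine transform, which leaves every Pearson correlation the downstream
analysis computes exactly invariant.

All randomness flows through one :func:`numpy.random.default_rng` stream
keyed by the scenario seed, so a scenario is fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix, GeneModel, GeneTable, SampleMeta

TIMEPOINTS = ["3h", "3d", "7d", "14d"]
CONDITIONS = ["mono", "co"]

ENZYME_CLASS_POOL = [
    "CYP450", "UDP-glucosyltransferase", "2OG-FeII-oxygenase",
    "O-methyltransferase", "terpene-synthase", "BAHD-acyltransferase",
    "dioxygenase", "short-chain-dehydrogenase",
]

DECOY_KINDS = ("no_copathway", "no_coexpression", "homologous")


@dataclass(frozen=True)
class PlantedCluster:
    """Specification of one planted biosynthetic gene cluster.

    ``kind`` is ``"true"`` for a cluster meant to survive every validation
    filter, or one of the decoy kinds from :func:`make_negative_cluster`,
    each violating exactly one criterion.
    """

    name: str
    size: int = 5
    has_p450: bool = True
    n_enzyme_classes: int = 3
    pathway_id: str = "PWY-0001"
    n_reactions: int = 3
    co_expressed: bool = True
    loading_range: tuple[float, float] = (0.85, 0.95)
    kind: str = "true"

    def __post_init__(self):
        if not (3 <= self.size <= 10):
            raise ValueError(f"cluster {self.name}: size must be in [3, 10]")
        if self.n_enzyme_classes < 1 or self.n_enzyme_classes > self.size:
            raise ValueError(f"cluster {self.name}: n_enzyme_classes out of range")
        if self.n_reactions < 1:
            raise ValueError(f"cluster {self.name}: n_reactions must be >= 1")


@dataclass(frozen=True)
class PlantedModule:
    """Specification of one planted co-expression module.

    Member loadings are drawn uniformly from ``loading_range``; the first
    ``n_hubs`` members load at ``hub_loading`` instead (the planted hubs).
    ``trait_link`` optionally names a planted cluster and a correlation r: the
    module's latent factor is then generated correlated with that cluster's
    factor at r, the generative analogue of a module-trait association.
    """

    name: str
    size: int
    loading_range: tuple[float, float] = (0.6, 0.9)
    n_hubs: int = 0
    hub_loading: float = 0.95
    trait_link: Optional[tuple[str, float]] = None
    eigen_profile: Optional[tuple[float, ...]] = None

    def __post_init__(self):
        if self.size < 1:
            raise ValueError(f"module {self.name}: size must be >= 1")
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"module {self.name}: loading_range must be in (0, 1]")
        if self.n_hubs > self.size:
            raise ValueError(f"module {self.name}: more hubs than members")


@dataclass(frozen=True)
class PlantedRegulator:
    """A gene outside a cluster that shares the cluster's latent factor.

    ``loading = 0`` plants a decoy regulator with pure-noise expression.
    """

    name: str
    cluster: str
    loading: float = 0.9


@dataclass(frozen=True)
class ScenarioConfig:
    n_genes: int = 560
    n_chroms: int = 5
    n_samples: int = 16
    planted_clusters: tuple[PlantedCluster, ...] = ()
    planted_modules: tuple[PlantedModule, ...] = ()
    planted_regulators: tuple[PlantedRegulator, ...] = ()
    noise_sd: float = 0.3
    background_enzyme_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.n_chroms < 1:
            raise ValueError("n_chroms must be >= 1")
        planted = (sum(c.size for c in self.planted_clusters)
                   + sum(m.size for m in self.planted_modules)
                   + len(self.planted_regulators))
        if self.n_genes < planted:
            raise ValueError(
                f"n_genes ({self.n_genes}) smaller than planted gene count ({planted})")
        names = ([c.name for c in self.planted_clusters]
                 + [m.name for m in self.planted_modules])
        if len(names) != len(set(names)):
            raise ValueError("planted structure names must be unique")
        for r in self.planted_regulators:
            if r.cluster not in {c.name for c in self.planted_clusters}:
                raise ValueError(f"regulator {r.name}: unknown cluster {r.cluster}")


@dataclass
class Scenario:
    """A generated scenario: all pipeline inputs plus the ground-truth ledger."""

    config: ScenarioConfig
    gene_table: GeneTable
    pathway_table: pd.DataFrame
    expression: ExpressionMatrix
    ledger: dict


def make_negative_cluster(kind: str, name: str | None = None, size: int = 4,
                          pathway_id: str = "PWY-DECOY") -> PlantedCluster:
    """Build a decoy cluster spec violating exactly one validation criterion.

    ``no_copathway``: members share a pathway but carry a single reaction id.
    ``no_coexpression``: members get independent noise expression profiles.
    ``homologous``: all members share one protein family (and one enzyme class).
    """
    if kind not in DECOY_KINDS:
        raise ValueError(f"unknown decoy kind: {kind!r}")
    name = name or f"decoy_{kind}"
    base = PlantedCluster(name=name, size=size, pathway_id=pathway_id,
                          n_reactions=max(2, size - 1), kind=kind)
    if kind == "no_copathway":
        return replace(base, n_reactions=1)
    if kind == "no_coexpression":
        return replace(base, co_expressed=False)
    # homologous: family assignment handled at generation; a single-family run
    # of one enzyme class is the natural shape of a tandem-duplication array.
    return replace(base, n_enzyme_classes=1, has_p450=False)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _sample_design(n_samples: int) -> list[SampleMeta]:
    metas = []
    i = 0
    for rep in range(1, 1 + max(1, -(-n_samples // (len(TIMEPOINTS) * len(CONDITIONS))))):
        for cond in CONDITIONS:
            for tp in TIMEPOINTS:
                if i >= n_samples:
                    return metas
                metas.append(SampleMeta(f"{cond}_{tp}_r{rep}", tp, cond, rep))
                i += 1
    return metas


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("degenerate latent factor with zero variance")
    return (v - v.mean()) / sd


def _cluster_classes(rng, spec: PlantedCluster) -> list[str]:
    pool = [c for c in ENZYME_CLASS_POOL if c != "CYP450"]
    classes = []
    if spec.has_p450:
        classes.append("CYP450")
    take = spec.n_enzyme_classes - len(classes)
    classes += list(rng.choice(pool, size=take, replace=False))
    # Cycle distinct classes over members so exactly n_enzyme_classes occur.
    return [classes[i % len(classes)] for i in range(spec.size)]


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate gene table, pathway annotation, expression and ledger.

    Planted cluster members are placed in adjacent genomic positions with
    small intergenic gaps (0.5-2.5 kb); background genes are separated by
    25-40 kb gaps so they can never satisfy a run definition tighter than
    ~20 kb on their own.  Placement raises if a chromosome cannot hold its
    allotted clusters (more cluster blocks than background anchor slots).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    samples = _sample_design(cfg.n_samples)
    n = cfg.n_samples

    # --- latent factors --------------------------------------------------
    cluster_factor: dict[str, np.ndarray] = {}
    for c in cfg.planted_clusters:
        cluster_factor[c.name] = _standardize(rng.standard_normal(n))
    module_factor: dict[str, np.ndarray] = {}
    for m in cfg.planted_modules:
        if m.eigen_profile is not None:
            if len(m.eigen_profile) != n:
                raise ValueError(f"module {m.name}: eigen_profile length != n_samples")
            module_factor[m.name] = _standardize(np.asarray(m.eigen_profile, float))
        elif m.trait_link is not None:
            target, r = m.trait_link
            if target not in cluster_factor:
                raise ValueError(f"module {m.name}: trait_link to unknown cluster {target}")
            g = _standardize(rng.standard_normal(n))
            module_factor[m.name] = _standardize(
                r * cluster_factor[target] + np.sqrt(1 - r ** 2) * g)
        else:
            module_factor[m.name] = _standardize(rng.standard_normal(n))

    # --- gene inventory ---------------------------------------------------
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"g{counter:05d}"

    fam_counter = 0

    def next_family() -> str:
        nonlocal fam_counter
        fam_counter += 1
        return f"FAM{fam_counter:04d}"

    z_rows: dict[str, np.ndarray] = {}
    gene_meta: dict[str, dict] = {}   # gene_id -> enzyme classes / families
    cluster_members: dict[str, list[str]] = {}
    module_members: dict[str, list[str]] = {}
    hub_ids: dict[str, list[str]] = {}
    pathway_rows: list[tuple[str, str, str]] = []

    for c in cfg.planted_clusters:
        classes = _cluster_classes(rng, c)
        shared_family = next_family() if c.kind == "homologous" else None
        members = []
        loadings = rng.uniform(*c.loading_range, size=c.size)
        reactions = [f"RXN-{c.name}-{i + 1}" for i in range(c.n_reactions)]
        for i in range(c.size):
            gid = next_id()
            members.append(gid)
            fam = shared_family if shared_family else next_family()
            gene_meta[gid] = {"classes": frozenset([classes[i]]),
                              "families": frozenset([fam])}
            if c.co_expressed:
                z = loadings[i] * cluster_factor[c.name] \
                    + rng.normal(0, cfg.noise_sd, n)
            else:
                z = rng.standard_normal(n)
            z_rows[gid] = z
            pathway_rows.append((gid, c.pathway_id, reactions[i % len(reactions)]))
        cluster_members[c.name] = members

    for m in cfg.planted_modules:
        members, hubs = [], []
        loadings = rng.uniform(*m.loading_range, size=m.size)
        loadings[: m.n_hubs] = m.hub_loading
        for i in range(m.size):
            gid = next_id()
            members.append(gid)
            if i < m.n_hubs:
                hubs.append(gid)
            gene_meta[gid] = {"classes": frozenset(), "families": frozenset([next_family()])}
            z_rows[gid] = loadings[i] * module_factor[m.name] \
                + rng.normal(0, cfg.noise_sd, n)
        module_members[m.name] = members
        hub_ids[m.name] = hubs

    regulator_ids: dict[str, str] = {}
    for r in cfg.planted_regulators:
        gid = next_id()
        regulator_ids[r.name] = gid
        gene_meta[gid] = {"classes": frozenset(), "families": frozenset([next_family()])}
        if r.loading > 0:
            z_rows[gid] = r.loading * cluster_factor[r.cluster] \
                + rng.normal(0, cfg.noise_sd, n)
        else:
            z_rows[gid] = rng.standard_normal(n)

    n_background = cfg.n_genes - len(z_rows)
    background_ids = []
    for _ in range(n_background):
        gid = next_id()
        background_ids.append(gid)
        if rng.random() < cfg.background_enzyme_fraction:
            cls = str(rng.choice(ENZYME_CLASS_POOL))
            gene_meta[gid] = {"classes": frozenset([cls]),
                              "families": frozenset([next_family()])}
            pathway_rows.append((
                gid,
                f"PWY-B{int(rng.integers(1, 41)):03d}",
                f"RXN-B{int(rng.integers(1, 121)):04d}",
            ))
        else:
            gene_meta[gid] = {"classes": frozenset(), "families": frozenset([next_family()])}
        z_rows[gid] = rng.standard_normal(n)

    # --- genomic placement ------------------------------------------------
    genes = _place_genes(rng, cfg, cluster_members, module_members,
                         regulator_ids, background_ids, gene_meta)

    # --- expression on the FPKM-like scale --------------------------------
    gene_order = sorted(z_rows)  # id order == creation order (zero-padded)
    base = rng.uniform(5.0, 50.0, size=len(gene_order))
    values = np.empty((len(gene_order), n))
    for i, gid in enumerate(gene_order):
        values[i] = np.clip(base[i] * (1.0 + 0.15 * z_rows[gid]), 0.0, None)
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(gene_order, name="gene_id"),
                     columns=[s.sample_id for s in samples]),
        samples,
    )

    pathway_table = pd.DataFrame(sorted(pathway_rows),
                                 columns=["gene_id", "pathway_id", "reaction_id"])

    ledger = {
        "seed": cfg.seed,
        "n_genes": cfg.n_genes,
        "n_samples": cfg.n_samples,
        "noise_sd": cfg.noise_sd,
        "clusters": [{
            "cluster_id": c.name,
            "kind": c.kind,
            "gene_ids": cluster_members[c.name],
            "pathway_id": c.pathway_id,
            "co_expressed": c.co_expressed,
            "has_p450": c.has_p450,
        } for c in cfg.planted_clusters],
        "modules": [{
            "label": m.name,
            "gene_ids": module_members[m.name],
            "hub_ids": hub_ids[m.name],
            "trait_link": (
                {"cluster": m.trait_link[0], "r": m.trait_link[1]}
                if m.trait_link else None),
        } for m in cfg.planted_modules],
        "regulators": [{
            "gene_id": regulator_ids[r.name],
            "cluster": r.cluster,
            "loading": r.loading,
        } for r in cfg.planted_regulators],
    }
    return Scenario(cfg, genes, pathway_table, expr, ledger)


def _place_genes(rng, cfg, cluster_members, module_members, regulator_ids,
                 background_ids, gene_meta) -> GeneTable:
    """Lay genes on chromosomes: cluster blocks adjacent, everything else sparse."""
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    loose: list[str] = []
    for members in module_members.values():
        loose.extend(members)
    loose.extend(regulator_ids.values())
    loose.extend(background_ids)

    per_chrom_loose: dict[str, list[str]] = {c: [] for c in chroms}
    for i, gid in enumerate(loose):
        per_chrom_loose[chroms[i % len(chroms)]].append(gid)

    cluster_names = list(cluster_members)
    per_chrom_blocks: dict[str, list[str]] = {c: [] for c in chroms}
    for i, name in enumerate(cluster_names):
        per_chrom_blocks[chroms[i % len(chroms)]].append(name)

    models = []
    for chrom in chroms:
        slots: list[tuple[str, object]] = [("gene", g) for g in per_chrom_loose[chrom]]
        blocks = per_chrom_blocks[chrom]
        if blocks and len(slots) + 1 < len(blocks):
            raise ValueError(
                f"{chrom}: cannot place {len(blocks)} cluster blocks among "
                f"{len(slots)} background genes")
        insert_at = sorted(rng.choice(len(slots) + 1, size=len(blocks),
                                      replace=False)) if blocks else []
        for offset, (pos, name) in enumerate(zip(insert_at, blocks)):
            slots.insert(pos + offset, ("block", name))
        pos = int(rng.integers(10_000, 50_000))
        for kind, payload in slots:
            if kind == "gene":
                gid = payload
                length = int(rng.integers(1_000, 5_000))
                models.append(_model(gid, chrom, pos, pos + length, rng, gene_meta))
                pos += length + int(rng.integers(25_000, 40_000))
            else:
                for gid in cluster_members[payload]:
                    length = int(rng.integers(1_000, 4_000))
                    models.append(_model(gid, chrom, pos, pos + length, rng, gene_meta))
                    pos += length + int(rng.integers(500, 2_500))
                pos += int(rng.integers(25_000, 40_000))
    return GeneTable(models)


def _model(gid, chrom, start, end, rng, gene_meta) -> GeneModel:
    return GeneModel(
        gene_id=gid, chrom=chrom, start=start, end=end,
        strand="+" if rng.random() < 0.5 else "-",
        enzyme_classes=gene_meta[gid]["classes"],
        family_ids=gene_meta[gid]["families"],
    )


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------

def write_fixture_bundle(scenario: Scenario, out_dir) -> dict[str, Path]:
    """Write the five pipeline input files plus the ground-truth ledger.

    Regenerating the same scenario from the same seed produces byte-identical
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out / "genes.tsv",
        "expression": out / "expression.tsv",
        "samples": out / "samples.tsv",
        "pathways": out / "pathways.tsv",
        "ledger": out / "ledger.json",
    }
    from .io_core import FLOAT_FORMAT

    scenario.gene_table.to_frame().to_csv(paths["genes"], sep="\t", index=False,
                                          lineterminator="\n")
    scenario.expression.values.to_csv(paths["expression"], sep="\t",
                                      float_format=FLOAT_FORMAT, lineterminator="\n")
    pd.DataFrame([{
        "sample_id": s.sample_id, "timepoint": s.timepoint,
        "condition": s.condition, "replicate": s.replicate,
    } for s in scenario.expression.samples]).to_csv(
        paths["samples"], sep="\t", index=False, lineterminator="\n")
    scenario.pathway_table.to_csv(paths["pathways"], sep="\t", index=False,
                                  lineterminator="\n")
    paths["ledger"].write_text(json.dumps(scenario.ledger, indent=2, sort_keys=True) + "\n")
    return paths


# ---------------------------------------------------------------------------
# Scenario presets: the study conditions exercised by tests and benchmarks
# ---------------------------------------------------------------------------

def default_scenario(seed: int = 0) -> ScenarioConfig:
    """Full-pipeline scenario: 4 true clusters, 3 single-defect decoys,
    3 modules (one trait-linked), planted regulators and hubs."""
    clusters = (
        PlantedCluster("momilactone", size=5, pathway_id="PWY-7477",
                       n_reactions=4),
        PlantedCluster("dibo_glucoside", size=4, pathway_id="PWY-6949",
                       n_reactions=3),
        PlantedCluster("quercetin_glucoside", size=6, pathway_id="PWY-7129",
                       n_reactions=4),
        PlantedCluster("flavonol", size=3, pathway_id="PWY-3101",
                       n_reactions=2, n_enzyme_classes=2),
        make_negative_cluster("no_copathway", pathway_id="PWY-D001"),
        make_negative_cluster("no_coexpression", pathway_id="PWY-D002"),
        make_negative_cluster("homologous", pathway_id="PWY-D003"),
    )
    modules = (
        PlantedModule("PM1", size=120, n_hubs=3,
                      trait_link=("momilactone", 0.9)),
        PlantedModule("PM2", size=80, n_hubs=3),
        PlantedModule("PM3", size=60, n_hubs=2),
    )
    regulators = (
        PlantedRegulator("reg1", "momilactone", 0.9),
        PlantedRegulator("reg2", "momilactone", 0.9),
        PlantedRegulator("reg_null", "momilactone", 0.0),
    )
    return ScenarioConfig(n_genes=560, planted_clusters=clusters,
                          planted_modules=modules,
                          planted_regulators=regulators, seed=seed)


def module_recovery_scenario(seed: int = 0) -> ScenarioConfig:
    """Three planted modules of sizes 120/80/60 at fixed loading 0.85,
    noise 0.3, 16 samples, plus unstructured background."""
    modules = tuple(
        PlantedModule(f"PM{i + 1}", size=s, loading_range=(0.85, 0.85))
        for i, s in enumerate((120, 80, 60)))
    return ScenarioConfig(n_genes=500, planted_modules=modules, seed=seed)


def trait_link_scenario(seed: int = 0) -> ScenarioConfig:
    """One module linked at r = 0.9 to a planted cluster's factor, one
    unlinked module, and two unlinked co-expressed clusters whose member
    traits are orthogonal to both modules."""
    clusters = (
        PlantedCluster("linked_bgc", size=3, pathway_id="PWY-7477",
                       n_reactions=2, n_enzyme_classes=2,
                       loading_range=(0.9, 0.95)),
        PlantedCluster("orthogonal_bgc", size=4, pathway_id="PWY-6949",
                       n_reactions=3, loading_range=(0.9, 0.95)),
        PlantedCluster("orthogonal_bgc2", size=4, pathway_id="PWY-6275",
                       n_reactions=3, loading_range=(0.9, 0.95)),
    )
    modules = (
        PlantedModule("PM1", size=80, loading_range=(0.7, 0.9),
                      trait_link=("linked_bgc", 0.9)),
        PlantedModule("PM2", size=60, loading_range=(0.7, 0.9)),
    )
    return ScenarioConfig(n_genes=280, planted_clusters=clusters,
                          planted_modules=modules, noise_sd=0.2, seed=seed)


def hub_recovery_scenario(seed: int = 0) -> ScenarioConfig:
    """Planted hubs at loading 0.95 over 0.4-0.7 background members,
    noise 0.3; each module trait-linked so the GS gate is live."""
    clusters = (
        PlantedCluster("bgc_a", size=4, pathway_id="PWY-7477", n_reactions=3,
                       loading_range=(0.9, 0.95)),
        PlantedCluster("bgc_b", size=4, pathway_id="PWY-7129", n_reactions=3,
                       loading_range=(0.9, 0.95)),
    )
    modules = (
        PlantedModule("PM1", size=60, loading_range=(0.4, 0.7), n_hubs=5,
                      hub_loading=0.95, trait_link=("bgc_a", 0.9)),
        PlantedModule("PM2", size=60, loading_range=(0.4, 0.7), n_hubs=5,
                      hub_loading=0.95, trait_link=("bgc_b", 0.9)),
    )
    return ScenarioConfig(n_genes=300, planted_clusters=clusters,
                          planted_modules=modules, seed=seed)


def pure_noise_scenario(seed: int = 0, n_genes: int = 300) -> ScenarioConfig:
    """No planted structure at all: every gene is background noise."""
    return ScenarioConfig(n_genes=n_genes, seed=seed)


def noiseless_scenario(seed: int = 0) -> ScenarioConfig:
    """Vanishing-noise limit: within-structure correlations approach 1."""
    cfg = default_scenario(seed)
    return replace(cfg, noise_sd=1e-9)
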