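"""Readers, writers and the shared tabular data model.

All genomic coordinates are 1-based inclusive (GFF3 convention) throughout the
package; no half-open conversion is ever exposed.  The canonical interchange
format is a simplified TSV gene table; GFF3 input is supported for ``gene``
features only, with enzyme-class and protein-family annotations read from
configurable attribute keys.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("clustermod.io")

#: Column order of the simplified TSV gene dialect.
GENE_TSV_COLUMNS = ["gene_id", "chrom", "start", "end", "strand",
                    "enzyme_classes", "family_ids"]

#: Fixed rendering precision for floats in every report (significant digits).
FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One annotated gene.

    ``enzyme_classes`` holds enzyme-class labels (e.g. ``CYP450``,
    ``UDP-glucosyltransferase``); an empty set marks a non-enzyme gene.
    ``family_ids`` holds protein-family labels used as the homology proxy.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    enzyme_classes: frozenset = frozenset()
    family_ids: frozenset = frozenset()

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) < start ({self.start})")

    @property
    def is_enzyme(self) -> bool:
        return len(self.enzyme_classes) > 0


class GeneTable:
    """An ordered collection of :class:`GeneModel`, sorted by (chrom, start).

    Gene ids are unique; duplicates raise at construction.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
        seen = {}
        for g in genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id: {g.gene_id}")
            seen[g.gene_id] = g
        self._genes: list[GeneModel] = genes
        self._by_id: dict[str, GeneModel] = seen

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self):
        return iter(self._genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene_id: {gene_id}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self._genes]

    def by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self._genes:
            out.setdefault(g.chrom, []).append(g)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "gene_id": g.gene_id, "chrom": g.chrom, "start": g.start,
            "end": g.end, "strand": g.strand,
            "enzyme_classes": ";".join(sorted(g.enzyme_classes)),
            "family_ids": ";".join(sorted(g.family_ids)),
        } for g in self._genes]
        return pd.DataFrame(rows, columns=GENE_TSV_COLUMNS)


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one expression sample.

    The emulated study design is a time course (3 h, 3 d, 7 d, 14 d) under two
    growth conditions (mono-culture vs co-culture) with two replicates.
    """

    sample_id: str
    timepoint: str = ""
    condition: str = ""
    replicate: int = 0


class ExpressionMatrix:
    """Genes × samples matrix of non-negative FPKM-like values.

    Wraps a :class:`pandas.DataFrame` (index = gene ids, columns = sample ids)
    plus optional per-sample metadata.  Rows that were entirely missing are
    dropped at read time; remaining missing cells are mean-imputed per gene by
    :meth:`imputed` before any correlation work.
    """

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleMeta] | None = None):
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene_ids in expression matrix: {dups[:5]}")
        if values.shape[1] < 3:
            raise ValueError(
                f"at least 3 samples required for correlation, got {values.shape[1]}")
        all_na = values.isna().all(axis=1)
        if all_na.any():
            raise ValueError(
                "rows with no finite value are not allowed; drop them at read time")
        if samples is not None:
            ids = [s.sample_id for s in samples]
            if ids != list(values.columns):
                raise ValueError("sample metadata does not match expression columns")
        self.values = values.astype(float)
        self.samples = list(samples) if samples is not None else None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values.index

    def row(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy()

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in gene_ids if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present], self.samples)

    def imputed(self) -> "ExpressionMatrix":
        """Mean-impute missing cells per gene (no-op when complete)."""
        if not self.values.isna().any().any():
            return self
        n_missing = int(self.values.isna().sum().sum())
        logger.warning("mean-imputing %d missing expression cells", n_missing)
        filled = self.values.apply(lambda r: r.fillna(r.mean()), axis=1)
        return ExpressionMatrix(filled, self.samples)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _split_multi(cell) -> frozenset:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text or text.lower() == "nan":
        return frozenset()
    return frozenset(p.strip() for p in text.split(";") if p.strip())


def read_gene_table(path, dialect: str = "tsv", *,
                    enzyme_attr: str = "enzyme_class",
                    family_attr: str = "family_id") -> GeneTable:
    """Read a gene annotation table (simplified TSV or GFF3 gene features).

    TSV dialect requires a header with at least gene_id/chrom/start/end;
    strand, enzyme_classes and family_ids are optional columns (semicolon
    separated sets).  GFF3 dialect reads features of type ``gene`` only, the
    ``ID`` attribute naming the gene and *enzyme_attr*/*family_attr* carrying
    comma-separated annotation values.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_gene_tsv(path)
    if dialect == "gff3":
        return _read_gene_gff3(path, enzyme_attr, family_attr)
    raise ValueError(f"unknown gene table dialect: {dialect!r}")


def _read_gene_tsv(path: Path) -> GeneTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    genes = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            gene = GeneModel(
                gene_id=str(row["gene_id"]),
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=str(row.get("strand", "+")) if "strand" in df.columns else "+",
                enzyme_classes=_split_multi(row.get("enzyme_classes")),
                family_ids=_split_multi(row.get("family_ids")),
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {line_no}: {exc}") from None
        genes.append(gene)
    return GeneTable(genes)


def _read_gene_gff3(path: Path, enzyme_attr: str, family_attr: str) -> GeneTable:
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="error")
    genes = []
    for feat in db.features_of_type("gene"):
        ids = feat.attributes.get("ID")
        if not ids:
            raise ValueError(f"{path}: gene feature without ID attribute "
                             f"at {feat.seqid}:{feat.start}")
        if feat.end < feat.start:
            raise ValueError(
                f"{path}: gene {ids[0]}: end ({feat.end}) < start ({feat.start})")
        genes.append(GeneModel(
            gene_id=ids[0],
            chrom=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand if feat.strand in "+-" else "+",
            enzyme_classes=frozenset(feat.attributes.get(enzyme_attr, [])),
            family_ids=frozenset(feat.attributes.get(family_attr, [])),
        ))
    return GeneTable(genes)


def read_sample_metadata(path) -> list[SampleMeta]:
    """Read a sample-metadata TSV: sample_id, timepoint, condition, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id")
    return [SampleMeta(
        sample_id=r["sample_id"],
        timepoint=str(r.get("timepoint", "") or ""),
        condition=str(r.get("condition", "") or ""),
        replicate=int(r["replicate"]) if "replicate" in df.columns and pd.notna(r.get("replicate")) else 0,
    ) for _, r in df.iterrows()]


def read_expression(path, sample_metadata_path=None) -> ExpressionMatrix:
    """Read an expression TSV (first column gene ids, remaining columns samples).

    Rows with no finite value are dropped with a logged count; a non-numeric
    cell raises naming its row and column; fewer than 3 sample columns is a
    hard error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: at least 3 samples required, got {df.shape[1]}")
    for col in df.columns:
        if df[col].dtype == object:
            numeric = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & numeric.isna()
            if bad.any():
                gene = df.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"{path}: non-numeric value {df.loc[gene, col]!r} "
                    f"at gene {gene!r}, sample {col!r}")
            df[col] = numeric
    all_na = df.isna().all(axis=1)
    if all_na.any():
        logger.warning("%s: dropped %d genes with no finite expression value",
                       path, int(all_na.sum()))
        df = df.loc[~all_na]
    samples = None
    if sample_metadata_path is not None:
        meta = {s.sample_id: s for s in read_sample_metadata(sample_metadata_path)}
        samples = [meta.get(c, SampleMeta(sample_id=c)) for c in df.columns]
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return ExpressionMatrix(df, samples)


def read_pathway_table(path) -> pd.DataFrame:
    """Read a pathway annotation TSV: gene_id, pathway_id, reaction_id.

    A gene may carry multiple (pathway, reaction) rows; all three fields must
    be non-empty.  Emulates E2P2/PathoLogic-style MetaCyc output consumed as a
    table.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "pathway_id", "reaction_id"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df[required]
    empty = df.isna().any(axis=1) | (df.apply(lambda c: c.str.strip() == "").any(axis=1))
    if empty.any():
        raise ValueError(f"{path}: {int(empty.sum())} rows with empty fields "
                         f"(first at line {int(np.argmax(empty.to_numpy())) + 2})")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _frame_to_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT,
              lineterminator="\n")


def config_hash(config: Mapping) -> str:
    """Stable sha256 of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(obj, path, format: str = "tsv") -> None:
    """Write a pipeline result with deterministic column order and precision.

    Dispatches on the object type; two writes of the same object are
    byte-identical.  Floats are rendered with 6 significant digits.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        if not isinstance(obj, Mapping):
            raise TypeError(f"JSON reports require a mapping, got {type(obj).__name__}")
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown report format: {format!r}")

    df = _as_report_frame(obj)
    _frame_to_tsv(df, path, index=False)


def _jsonify(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (set, frozenset)):
        return sorted(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    if dataclasses.is_dataclass(value):
        return dataclasses.asdict(value)
    raise TypeError(f"not JSON serializable: {type(value).__name__}")


def _as_report_frame(obj) -> pd.DataFrame:
    """Render a known result object as a DataFrame (registry for write_report)."""
    # Local imports: the result types live in the stage modules.
    from .cluster_scan import CandidateCluster, clusters_to_frame
    from .copathway import CopathwayEvidence, copathway_report
    from .coexpr import ClusterCoexprEvidence, coexpr_report
    from .network import ModuleSet, ModuleTraitResult
    from .hubs import HubRecord, hub_records_to_frame

    if isinstance(obj, pd.DataFrame):
        return obj
    if isinstance(obj, GeneTable):
        return obj.to_frame()
    if isinstance(obj, ExpressionMatrix):
        return obj.values.reset_index()
    if isinstance(obj, ModuleSet):
        return obj.to_frame()
    if isinstance(obj, ModuleTraitResult):
        return obj.to_frame()
    if isinstance(obj, (list, tuple)) and obj:
        first = obj[0]
        if isinstance(first, CandidateCluster):
            return clusters_to_frame(obj)
        if isinstance(first, CopathwayEvidence):
            return copathway_report(obj)
        if isinstance(first, ClusterCoexprEvidence):
            return coexpr_report(obj)
        if isinstance(first, HubRecord):
            return hub_records_to_frame(obj)
    raise TypeError(f"write_report does not know how to render {type(obj).__name__}")
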