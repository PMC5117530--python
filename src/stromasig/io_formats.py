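"""On-disk formats and platform merging for expression compendia.

Everything downstream works on gene-by-sample matrices of log2 intensities.
This module owns the containers (:class:`ExpressionMatrix`,
:class:`GeneSetCollection`, probe maps, sample annotations), their
tab-separated text serialisations, and the two platform-integration steps
used when paired arrays cover complementary probe sets:

* union/maximum merge of paired platforms (one array pair per sample), and
* many-to-one collapse of probe-level rows to gene-level rows.

All text is UTF-8, tab-separated, ``.`` decimal separator. Floats are
written with 17 significant digits so that a write/read round trip is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("stromasig")

_FLOAT_FORMAT = "%.17g"

ANNOTATION_COLUMNS = ("sample_id", "cell_type", "lineage", "tissue", "batch")


class ExpressionMatrix:
    """Gene-by-sample matrix of log2 intensities.

    Wraps a pandas DataFrame (rows = genes, columns = samples) and enforces
    the container invariants: unique gene ids, unique sample ids, all values
    finite.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        values = data.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            bad = data.index[~np.isfinite(values).all(axis=1)][:5].tolist()
            raise ValueError(f"non-finite values in rows: {bad}")
        self.data = data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)])

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.data.equals(other.data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples)"


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional descriptions (GMT-shaped)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, genes: Iterable[str], description: str = "") -> None:
        genes = list(dict.fromkeys(genes))  # dedupe, keep order
        if name in self.sets:
            raise ValueError(f"duplicate gene-set name: {name!r}")
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = genes
        self.descriptions[name] = description

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def as_sets(self) -> dict[str, set[str]]:
        return {name: set(genes) for name, genes in self.sets.items()}


# ---------------------------------------------------------------------------
# Expression matrix TSV
# ---------------------------------------------------------------------------

def write_matrix(mat: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV: header = sample ids, first column = gene ids."""
    mat.data.to_csv(path, sep="\t", index_label="gene_id",
                    float_format=_FLOAT_FORMAT)


def read_matrix(path) -> ExpressionMatrix:
    """Read a TSV expression matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return ExpressionMatrix(df)


# ---------------------------------------------------------------------------
# Sample annotation TSV
# ---------------------------------------------------------------------------

def validate_annotation(ann: pd.DataFrame,
                        mat: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Check an annotation table: required columns, matching sample ids."""
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise ValueError(f"annotation missing columns: {missing_cols}")
    if ann["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in annotation")
    if ann["batch"].isna().any():
        raise ValueError("every sample must have a batch")
    if mat is not None:
        ann_ids = set(ann["sample_id"])
        mat_ids = set(mat.sample_ids)
        if ann_ids != mat_ids:
            raise ValueError(
                "annotation sample ids do not match matrix: "
                f"only-in-annotation={sorted(ann_ids - mat_ids)[:3]}, "
                f"only-in-matrix={sorted(mat_ids - ann_ids)[:3]}")
    return ann


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    return validate_annotation(ann)


# ---------------------------------------------------------------------------
# Probe-to-gene map
# ---------------------------------------------------------------------------

def read_probe_map(path) -> dict[str, str]:
    """Read a 2-column probe->gene TSV; a probe mapping to 2 genes errors."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValueError("probe map must have exactly 2 columns")
    probes, genes = df.iloc[:, 0], df.iloc[:, 1]
    mapping: dict[str, str] = {}
    for probe, gene in zip(probes, genes):
        if probe in mapping and mapping[probe] != gene:
            raise ValueError(f"probe {probe!r} maps to multiple genes")
        mapping[probe] = gene
    return mapping


def write_probe_map(mapping: Mapping[str, str], path) -> None:
    pd.DataFrame({"probe_id": list(mapping), "gene_id": list(mapping.values())}
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Platform merge and probe collapse
# ---------------------------------------------------------------------------

def merge_paired_platforms(mat_a: ExpressionMatrix,
                           mat_b: ExpressionMatrix) -> ExpressionMatrix:
    """Union the features of two paired platforms, keeping the brighter signal.

    Both matrices must cover the same samples (one array pair per sample).
    The merged feature set is the union of both feature sets; where a
    feature was measured on both platforms the elementwise maximum is kept,
    otherwise the single measurement is carried through. The operation is
    commutative, associative and idempotent.
    """
    if set(mat_a.sample_ids) != set(mat_b.sample_ids):
        raise ValueError("paired platforms must share identical sample ids")
    b = mat_b.data[mat_a.sample_ids]  # align sample order to A
    all_features = sorted(set(mat_a.gene_ids) | set(mat_b.gene_ids))
    a_full = mat_a.data.reindex(all_features)
    b_full = b.reindex(all_features)
    # feature in both -> max; feature in one -> that value (NaN loses to any value)
    merged = a_full.where(a_full.ge(b_full.fillna(-np.inf)), b_full)
    return ExpressionMatrix(merged)


def collapse_probes_to_genes(mat: ExpressionMatrix,
                             probe_map: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene (per-sample median).

    Probes absent from the map are dropped (their count is logged); the
    result is invariant to the probe row order.
    """
    if not probe_map:
        raise ValueError("probe map is empty")
    mapped = [p for p in mat.gene_ids if p in probe_map]
    n_dropped = mat.shape[0] - len(mapped)
    if not mapped:
        raise ValueError("no matrix feature is present in the probe map")
    if n_dropped:
        logger.warning("collapse_probes_to_genes: dropped %d unmapped probes",
                       n_dropped)
    sub = mat.data.loc[mapped]
    genes = pd.Series([probe_map[p] for p in mapped], index=sub.index)
    collapsed = sub.groupby(genes, sort=True).median()
    return ExpressionMatrix(collapsed)


# ---------------------------------------------------------------------------
# GMT gene-set files
# ---------------------------------------------------------------------------

def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            members = "\t".join(collection.sets[name])
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_gmt(path) -> GeneSetCollection:
    collection = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    "at least one member")
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            collection.add(name, members, desc)
    return collection
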