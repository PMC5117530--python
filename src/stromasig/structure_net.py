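"""Global structure analyses and the thresholded coexpression network.

Three views of compendium structure:

* PCA with either genes or samples as variables (SVD of the centered,
  optionally scaled matrix; variance fractions from squared singular
  values);
* sample-to-sample distances defined as the Euclidean distance between
  rows of the sample-sample Pearson correlation matrix, clustered with
  average linkage (UPGMA);
* a gene coexpression network keeping every unordered gene pair whose
  Pearson correlation reaches a stringent threshold (default r >= 0.95,
  signed; an absolute-value variant is available), exported in
  Cytoscape-compatible SIF and edge-list dialects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .io_formats import ExpressionMatrix, _FLOAT_FORMAT

logger = logging.getLogger("stromasig")


@dataclass
class PCAResult:
    orientation: str                  # "samples-as-variables" | "genes-as-variables"
    scores: pd.DataFrame              # observations x components
    variance_fraction: np.ndarray
    cumulative_variance: np.ndarray


@dataclass
class CoexpressionNetwork:
    """Undirected gene graph; edge attribute ``r`` is the Pearson correlation."""

    graph: nx.Graph
    threshold: float
    absolute: bool = False
    node_labels: dict[str, str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, float]]:
        return [(min(a, b), max(a, b), d["r"])
                for a, b, d in self.graph.edges(data=True)]


_ORIENTATIONS = ("samples-as-variables", "genes-as-variables")


def pca(mat: ExpressionMatrix, orientation: str = "genes-as-variables",
        center: bool = True, scale: bool = False) -> PCAResult:
    """Principal components with genes or samples as variables.

    ``genes-as-variables``: observations are samples, variables are genes
    (the usual sample-structure view). ``samples-as-variables``: the
    transpose. Scores come from the SVD of the column-centered (and
    optionally unit-scaled) observation matrix; variance fractions are the
    normalised squared singular values.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    if orientation == "genes-as-variables":
        x = mat.values.T            # samples x genes
        obs_ids = mat.sample_ids
    else:
        x = mat.values              # genes x samples
        obs_ids = mat.gene_ids
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 observations and >= 2 variables")
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            names = (mat.gene_ids if orientation == "genes-as-variables"
                     else mat.sample_ids)
            bad = [n for n, s in zip(names, sd) if s == 0]
            raise ValueError(f"constant variables cannot be scaled: {bad[:5]}")
        x = x / sd
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s ** 2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    scores = pd.DataFrame(u * s, index=obs_ids,
                          columns=[f"PC{i + 1}" for i in range(s.size)])
    return PCAResult(orientation=orientation, scores=scores,
                     variance_fraction=frac,
                     cumulative_variance=np.cumsum(frac))


def correlation_distance_matrix(mat: ExpressionMatrix) -> pd.DataFrame:
    """Euclidean distances between rows of the sample correlation matrix.

    Samples whose expression vector has zero variance have no defined
    correlation and raise an error naming the sample.
    """
    if mat.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    x = mat.values
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = [s for s, v in zip(mat.sample_ids, sd) if v == 0]
        raise ValueError(f"zero-variance samples: {bad[:5]}")
    corr = np.corrcoef(x.T)
    dist = squareform(pdist(corr, metric="euclidean"))
    return pd.DataFrame(dist, index=mat.sample_ids, columns=mat.sample_ids)


def hcluster(distances: pd.DataFrame, method: str = "average") -> np.ndarray:
    """Agglomerative clustering (UPGMA by default) of a distance matrix.

    Returns the scipy linkage matrix; merge order is deterministic for a
    given input ordering (nearest pair first, earlier index on ties).
    """
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    condensed = squareform(d, checks=False)
    return hierarchy.linkage(condensed, method=method)


def coexpression_network(mat: ExpressionMatrix,
                         genes: Sequence[str] | None = None,
                         r_min: float = 0.95,
                         absolute: bool = False,
                         node_labels: Mapping[str, str] | None = None
                         ) -> CoexpressionNetwork:
    """Thresholded Pearson coexpression network over a gene subset.

    Keeps every unordered gene pair with r >= r_min (positive
    correlations only unless ``absolute``, in which case |r| >= r_min).
    Zero-variance genes are excluded with a warning; genes without any
    retained edge do not appear as nodes.
    """
    if not 0 < r_min <= 1:
        raise ValueError("r_min must be in (0, 1]")
    if mat.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    sub = mat if genes is None else mat.subset_genes(genes)
    x = sub.values
    sd = x.std(axis=1)
    if np.any(sd == 0):
        dropped = int((sd == 0).sum())
        logger.warning("coexpression_network: %d zero-variance genes excluded",
                       dropped)
        keep = sd > 0
        x = x[keep]
        gene_ids = [g for g, k in zip(sub.gene_ids, keep) if k]
    else:
        gene_ids = sub.gene_ids
    graph = nx.Graph()
    if len(gene_ids) >= 2:
        corr = np.corrcoef(x)
        np.clip(corr, -1.0, 1.0, out=corr)
        score = np.abs(corr) if absolute else corr
        iu = np.triu_indices(len(gene_ids), k=1)
        hits = score[iu] >= r_min
        for i, j, r in zip(iu[0][hits], iu[1][hits], corr[iu][hits]):
            graph.add_edge(gene_ids[i], gene_ids[j], r=float(r))
    labels = dict(node_labels or {})
    for node in graph.nodes:
        if node in labels:
            graph.nodes[node]["label"] = labels[node]
    return CoexpressionNetwork(graph=graph, threshold=r_min,
                               absolute=absolute, node_labels=labels)


# ---------------------------------------------------------------------------
# Network export / import
# ---------------------------------------------------------------------------

_FORMATS = ("sif", "edgelist", "graphml")


def export_network(net: CoexpressionNetwork, path,
                   fmt: str = "edgelist") -> None:
    """Write a network as SIF, edge-list TSV, or GraphML.

    SIF lines read ``geneA coexp geneB``; the edge-list dialect carries
    the correlation (``geneA\\tgeneB\\tr``). A sidecar node attribute
    table (``<path>.nodes.tsv``) carries CD-marker / transcription-factor
    labels when present.
    """
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {_FORMATS}")
    if net.n_edges == 0:
        raise ValueError("refusing to export an empty network")
    path = Path(path)
    edges = sorted(net.edges())
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for a, b, _ in edges:
                fh.write(f"{a}\tcoexp\t{b}\n")
    elif fmt == "edgelist":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene_a\tgene_b\tr\n")
            for a, b, r in edges:
                fh.write(f"{a}\t{b}\t{_FLOAT_FORMAT % r}\n")
    else:
        nx.write_graphml(net.graph, path)
    if net.node_labels:
        with open(f"{path}.nodes.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene_id\tlabel\n")
            for node in sorted(net.graph.nodes):
                label = net.node_labels.get(node, "")
                fh.write(f"{node}\t{label}\n")


def read_network_edgelist(path, threshold: float = 0.0
                          ) -> CoexpressionNetwork:
    """Re-import an edge-list TSV written by :func:`export_network`."""
    graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_a", "gene_b", "r"]:
            raise ValueError("not a stromasig edge-list file")
        for line in fh:
            a, b, r = line.rstrip("\n").split("\t")
            graph.add_edge(a, b, r=float(r))
    return CoexpressionNetwork(graph=graph, threshold=threshold)


def read_network_sif(path) -> CoexpressionNetwork:
    """Re-import a SIF file (edge correlations are not stored in SIF)."""
    graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 or parts[1] != "coexp":
                raise ValueError(f"unexpected SIF line: {line!r}")
            graph.add_edge(parts[0], parts[2], r=np.nan)
    return CoexpressionNetwork(graph=graph, threshold=0.0)


def write_distance_matrix(dist: pd.DataFrame, path) -> None:
    dist.to_csv(path, sep="\t", index_label="sample_id",
                float_format=_FLOAT_FORMAT)


def write_pca_result(res: PCAResult, path) -> None:
    out = res.scores.copy()
    out.to_csv(path, sep="\t", index_label="observation",
               float_format=_FLOAT_FORMAT)
    summary = pd.DataFrame({
        "component": [f"PC{i + 1}" for i in range(res.variance_fraction.size)],
        "variance_fraction": res.variance_fraction,
        "cumulative_variance": res.cumulative_variance})
    summary.to_csv(f"{path}.variance.tsv", sep="\t", index=False,
                   float_format=_FLOAT_FORMAT)
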