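"""Set algebra for signature derivation and marker-panel enrichment.

Signatures are derived purely by set operations on stable DE gene lists:

* a *tissue-specific* signature is the intersection of the up-lists of one
  stromal class against every other stromal class;
* the *lineage core* signature intersects the up-lists of each tissue
  class against the out-of-lineage population, then the up-list from an
  independent meta-analysis contrast, then an externally derived
  expression footprint.

Marker-panel enrichment (CD antigens, cytokine panels) uses the upper-tail
hypergeometric test: with a universe of N genes of which K belong to the
panel, the probability that a list of n genes contains k or more panel
members by chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from scipy import stats

from .io_formats import GeneSetCollection

logger = logging.getLogger("stromasig")


@dataclass
class EnrichmentResult:
    """Hypergeometric overlap of a gene list with a marker panel."""

    panel: str
    universe_size: int   # N
    panel_size: int      # K (within universe)
    list_size: int       # n (within universe)
    overlap: int         # k
    p_value: float       # P(X >= k)
    overlap_genes: list[str] = field(default_factory=list)


@dataclass
class SignatureReport:
    """Provenance-carrying record of a set-algebraic derivation."""

    name: str
    inputs: dict[str, int]                 # input set name -> size
    stages: list[tuple[str, int]]          # (stage description, size after)
    members: set[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)
    multi_set_genes: set[str] = field(default_factory=set)


def tissue_specific_signature(up_lists: Mapping[str, Iterable[str]]
                              ) -> SignatureReport:
    """Genes up-regulated against *every* other stromal class.

    ``up_lists`` maps a comparison label (e.g. ``"BM-MSC_vs_FIB"``) to the
    stable up-list of that comparison; the signature is the intersection
    of all supplied lists.
    """
    if len(up_lists) < 2:
        raise ValueError("need at least 2 up-lists to intersect")
    sets = {name: set(genes) for name, genes in up_lists.items()}
    names = list(sets)
    result = set.intersection(*sets.values())
    stages = []
    running: set[str] | None = None
    for name in names:
        running = sets[name] if running is None else running & sets[name]
        stages.append((f"after {name}", len(running)))
    provenance = {g: [n for n in names if g in sets[n]] for g in result}
    return SignatureReport(name="tissue_specific",
                           inputs={n: len(s) for n, s in sets.items()},
                           stages=stages, members=result,
                           provenance=provenance)


def lineage_core_signature(tissue_up_lists: Mapping[str, Iterable[str]],
                           meta_up: Iterable[str] | None = None,
                           footprint: Iterable[str] | None = None
                           ) -> SignatureReport:
    """Conservative lineage signature from the cross-flow of up-lists.

    Intersects the per-tissue out-of-lineage up-lists, then the
    meta-analysis up-list, then the expression footprint. A missing
    (None) meta list or footprint stage is skipped and logged; the size
    after every executed stage is recorded.
    """
    if len(tissue_up_lists) < 2:
        raise ValueError("need at least 2 tissue up-lists")
    sets = {name: set(genes) for name, genes in tissue_up_lists.items()}
    inputs = {n: len(s) for n, s in sets.items()}
    stages: list[tuple[str, int]] = []
    running: set[str] | None = None
    for name, s in sets.items():
        running = s if running is None else running & s
        stages.append((f"after {name}", len(running)))
    for label, extra in (("meta_up", meta_up), ("footprint", footprint)):
        if extra is None:
            logger.info("lineage_core_signature: %s not supplied, skipped", label)
            continue
        extra = set(extra)
        inputs[label] = len(extra)
        running = running & extra
        stages.append((f"after {label}", len(running)))
    provenance = {g: [n for n, s in sets.items() if g in s] for g in running}
    return SignatureReport(name="lineage_core", inputs=inputs, stages=stages,
                           members=running, provenance=provenance)


def panel_enrichment(gene_list: Iterable[str], panel: Iterable[str],
                     universe: Iterable[str],
                     panel_name: str = "panel") -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of a panel in a gene list.

    Panel and list members outside the universe are dropped with a
    warning; p = P(X >= k) for X ~ Hypergeometric(N, K, n), evaluated via
    the log-gamma based survival function.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    panel_all, list_all = set(panel), set(gene_list)
    panel_in = panel_all & universe
    list_in = list_all & universe
    if len(panel_in) < len(panel_all):
        logger.warning("panel %r: %d members outside the universe dropped",
                       panel_name, len(panel_all) - len(panel_in))
    if len(list_in) < len(list_all):
        logger.warning("gene list: %d members outside the universe dropped",
                       len(list_all) - len(list_in))
    n_total, n_panel, n_list = len(universe), len(panel_in), len(list_in)
    overlap = sorted(panel_in & list_in)
    k = len(overlap)
    # P(X >= k); sf(k-1) is exact for integer k, and P(X >= 0) = 1
    p = float(stats.hypergeom.sf(k - 1, n_total, n_panel, n_list))
    p = min(max(p, 5e-324), 1.0)
    return EnrichmentResult(panel=panel_name, universe_size=n_total,
                            panel_size=n_panel, list_size=n_list,
                            overlap=k, p_value=p, overlap_genes=overlap)


def overlap_report(signature: Iterable[str],
                   collection: GeneSetCollection) -> SignatureReport:
    """Overlap of a signature with each set of a published collection.

    Genes appearing in two or more published sets are flagged (the
    usual bold-face convention of overlap tables).
    """
    signature = set(signature)
    if not signature:
        raise ValueError("empty signature")
    published = collection.as_sets()
    overlaps = {name: signature & members for name, members in published.items()}
    counts: dict[str, int] = {}
    for members in overlaps.values():
        for g in members:
            counts[g] = counts.get(g, 0) + 1
    multi = {g for g, c in counts.items() if c >= 2}
    overlapping = set().union(*overlaps.values()) if overlaps else set()
    provenance = {g: [n for n, m in overlaps.items() if g in m]
                  for g in overlapping}
    return SignatureReport(
        name="overlap_report",
        inputs={"signature": len(signature),
                **{n: len(m) for n, m in published.items()}},
        stages=[(f"overlap with {n}", len(m)) for n, m in overlaps.items()],
        members=signature, provenance=provenance, multi_set_genes=multi)


def write_signature_report(report: SignatureReport, path) -> None:
    """Plain TSV: gene, provenance (semicolon-joined), multi-set flag."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tsources\tin_multiple_sets\n")
        for gene in sorted(report.members):
            sources = ";".join(report.provenance.get(gene, []))
            flag = "yes" if gene in report.multi_set_genes else "no"
            fh.write(f"{gene}\t{sources}\t{flag}\n")
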