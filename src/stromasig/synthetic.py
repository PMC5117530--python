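"""Synthetic expression compendia with planted ground truth.

Emulates the statistical structure of a multi-series stromal/hematopoietic
expression compendium so that every downstream step (normalization,
stability-resampled differential expression, signature set algebra, panel
enrichment, coexpression networks) can be tested against a known truth:

* several cell classes in two lineages (mesenchymal stromal classes of
  different tissue origins, fibroblasts, and an out-of-lineage
  hematopoietic population), each with its own sample count;
* per-series (batch) additive per-gene offsets, samples assigned to
  batches round-robin;
* per-gene noise variances drawn from a scaled inverse-chi-square prior
  (the same hierarchical model the moderated t-test assumes), so
  hyperparameter recovery is a meaningful test;
* planted up/down-regulated gene blocks per contrast, disjoint across
  contrasts, with a configurable log2 effect size;
* designated marker panels (CD-like, cytokine-like) with a controlled
  overlap with the planted signatures;
* per-class growth records with known true doubling times.

The generator is fully deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexpr import GroupContrast
from .growth import GrowthRecord
from .io_formats import (ExpressionMatrix, GeneSetCollection, write_annotation,
                         write_gmt, write_matrix)

logger = logging.getLogger("stromasig")

MESENCHYMAL = "mesenchymal"
HEMATOPOIETIC = "hematopoietic"
_LINEAGES = (MESENCHYMAL, HEMATOPOIETIC)


@dataclass(frozen=True)
class CellClass:
    name: str
    lineage: str
    n_samples: int
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.lineage not in _LINEAGES:
            raise ValueError(f"lineage must be one of {_LINEAGES}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class ContrastPlan:
    """A planted contrast: ``target_vs_reference`` label plus block sizes.

    ``label`` is ``"<target>_vs_<reference>"`` where <target> names a cell
    class, a lineage, or a comma-separated list of classes, and
    <reference> may also be ``"rest"``. Planted up genes get ``+effect``
    added to every target-side class mean, down genes ``-effect``; the
    reference side is untouched, so the true logFC of the contrast equals
    the effect size.
    """

    label: str
    n_up: int
    n_down: int
    effect: float

    def __post_init__(self) -> None:
        if "_vs_" not in self.label:
            raise ValueError("contrast label must be '<target>_vs_<reference>'")
        if self.n_up < 0 or self.n_down < 0:
            raise ValueError("block sizes must be >= 0")
        if self.effect < 0:
            raise ValueError("effect size must be >= 0")

    @property
    def target(self) -> str:
        return self.label.split("_vs_")[0]


@dataclass(frozen=True)
class PanelPlan:
    name: str
    size: int
    overlap_with_signatures: float  # fraction of the panel drawn from planted genes

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("panel size must be >= 1")
        if not 0 <= self.overlap_with_signatures <= 1:
            raise ValueError("overlap fraction must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic compendium."""

    n_genes: int = 2000
    cell_classes: tuple[CellClass, ...] = (
        CellClass("BM-MSC", MESENCHYMAL, 20, tissue="bone marrow"),
        CellClass("AD-MSC", MESENCHYMAL, 10, tissue="adipose"),
        CellClass("PL-MSC", MESENCHYMAL, 10, tissue="placenta"),
        CellClass("FIB", MESENCHYMAL, 10, tissue="skin"),
        CellClass("HSPC", HEMATOPOIETIC, 10, tissue="bone marrow"),
    )
    n_batches: int = 3
    batch_sd: float = 0.5            # log2 units
    signature_plan: tuple[ContrastPlan, ...] = (
        ContrastPlan("mesenchymal_vs_HSPC", 150, 150, 1.5),
        ContrastPlan("BM-MSC_vs_rest", 40, 40, 1.5),
        ContrastPlan("AD-MSC_vs_rest", 30, 30, 1.5),
        ContrastPlan("PL-MSC_vs_rest", 40, 40, 1.5),
        ContrastPlan("FIB_vs_rest", 30, 30, 1.5),
    )
    noise_prior: tuple[float, float] = (4.0, 0.05)   # (d0, s0_sq), log2^2 units
    panel_plan: tuple[PanelPlan, ...] = (
        PanelPlan("CD_like", 80, 0.30),
        PanelPlan("cytokine_like", 60, 0.25),
    )
    baseline_mean: float = 8.0       # log2 units
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_batches < 1:
            raise ValueError("counts must be >= 1")
        if not self.cell_classes:
            raise ValueError("cell class list is empty")
        if len({c.name for c in self.cell_classes}) != len(self.cell_classes):
            raise ValueError("duplicate cell class names")
        d0, s0 = self.noise_prior
        if d0 <= 0 or s0 <= 0:
            raise ValueError("noise prior hyperparameters must be positive")
        planted = sum(p.n_up + p.n_down for p in self.signature_plan)
        if planted > self.n_genes:
            raise ValueError(
                f"signature plan requests {planted} genes but only "
                f"{self.n_genes} exist")

    @property
    def n_samples(self) -> int:
        return sum(c.n_samples for c in self.cell_classes)

    def class_names(self, lineage: str | None = None) -> list[str]:
        return [c.name for c in self.cell_classes
                if lineage is None or c.lineage == lineage]


@dataclass
class PlantedTruth:
    """Ground truth emitted with every simulated dataset."""

    assignments: pd.DataFrame    # gene_id, contrast, direction, logfc
    variances: pd.Series         # per-gene true noise variance
    panels: dict[str, list[str]] = field(default_factory=dict)

    def genes(self, contrast: str, direction: str) -> set[str]:
        a = self.assignments
        rows = a[(a["contrast"] == contrast) & (a["direction"] == direction)]
        return set(rows["gene_id"])

    def planted_genes(self) -> set[str]:
        return set(self.assignments["gene_id"])

    def direction_of(self, gene: str, contrast: str) -> str:
        a = self.assignments
        rows = a[(a["gene_id"] == gene) & (a["contrast"] == contrast)]
        return rows["direction"].iloc[0] if len(rows) else "null"


def _resolve_classes(token: str, config: SimulationConfig,
                     exclude: Sequence[str] = ()) -> list[str]:
    names = set(config.class_names())
    if token == "rest":
        return [n for n in config.class_names() if n not in exclude]
    if token in _LINEAGES:
        return config.class_names(lineage=token)
    chosen = [t.strip() for t in token.split(",")]
    unknown = [t for t in chosen if t not in names]
    if unknown:
        raise ValueError(f"unknown cell class(es) in contrast label: {unknown}")
    return chosen


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[ExpressionMatrix, pd.DataFrame, PlantedTruth]:
    """Generate (expression matrix, sample annotation, planted truth).

    Per gene g and sample s of class c in batch b:

        x[g, s] = baseline_g + shift[g, c] + batch_offset[g, b] + eps
        eps ~ N(0, sigma_g^2),  sigma_g^2 ~ s0_sq * d0 / chi2(d0)

    Planted blocks are sampled without replacement from non-overlapping
    index ranges of a seeded gene permutation, so blocks of different
    contrasts never overlap.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    gene_ids = np.array([f"G{i + 1:05d}" for i in range(n_genes)])
    d0, s0 = config.noise_prior
    variances = s0 * d0 / rng.chisquare(d0, size=n_genes)
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, n_genes)

    # disjoint planted blocks from a seeded permutation
    perm = rng.permutation(n_genes)
    cursor = 0
    class_names = config.class_names()
    shift = {c: np.zeros(n_genes) for c in class_names}
    truth_rows: list[dict] = []
    for plan in config.signature_plan:
        targets = _resolve_classes(plan.target, config)
        for direction, size, sign in (("up", plan.n_up, +1.0),
                                      ("down", plan.n_down, -1.0)):
            idx = perm[cursor:cursor + size]
            cursor += size
            for c in targets:
                shift[c][idx] += sign * plan.effect
            for g in gene_ids[idx]:
                truth_rows.append({"gene_id": g, "contrast": plan.label,
                                   "direction": direction,
                                   "logfc": sign * plan.effect})

    samples, ann_rows = [], []
    class_of: list[str] = []
    for cls in config.cell_classes:
        for i in range(cls.n_samples):
            sid = f"{cls.name}_s{i + 1:02d}"
            samples.append(sid)
            class_of.append(cls.name)
            ann_rows.append({"sample_id": sid, "cell_type": cls.name,
                             "lineage": cls.lineage, "tissue": cls.tissue,
                             "batch": ""})
    batches = [f"B{j % config.n_batches + 1}" for j in range(len(samples))]
    for row, b in zip(ann_rows, batches):
        row["batch"] = b
    batch_ids = sorted(set(batches))
    batch_offsets = {b: rng.normal(0.0, config.batch_sd, n_genes)
                     for b in batch_ids}

    noise = rng.normal(0.0, 1.0, size=(n_genes, len(samples)))
    noise *= np.sqrt(variances)[:, None]
    values = np.empty((n_genes, len(samples)))
    for j, (cls, b) in enumerate(zip(class_of, batches)):
        values[:, j] = baselines + shift[cls] + batch_offsets[b] + noise[:, j]

    mat = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=samples))
    ann = pd.DataFrame(ann_rows)
    truth = PlantedTruth(
        assignments=pd.DataFrame(
            truth_rows, columns=["gene_id", "contrast", "direction", "logfc"]),
        variances=pd.Series(variances, index=gene_ids, name="variance"))
    return mat, ann, truth


def contrast_for_plan(plan_label: str, config: SimulationConfig,
                      ann: pd.DataFrame) -> GroupContrast:
    """Materialise a planted contrast label into sample-id groups."""
    target_token, ref_token = plan_label.split("_vs_")
    targets = _resolve_classes(target_token, config)
    refs = _resolve_classes(ref_token, config, exclude=targets)
    group_a = ann.loc[ann["cell_type"].isin(targets), "sample_id"].tolist()
    group_b = ann.loc[ann["cell_type"].isin(refs), "sample_id"].tolist()
    return GroupContrast(name=plan_label, group_a=group_a, group_b=group_b)


# ---------------------------------------------------------------------------
# Marker panels
# ---------------------------------------------------------------------------

def make_panel_collection(truth: PlantedTruth, config: SimulationConfig
                          ) -> GeneSetCollection:
    """Marker panels with a controlled overlap with the planted signatures.

    For each panel of size m with overlap fraction f, round(f * m) genes
    are drawn from the planted signature pool and the rest from null
    genes; panel memberships are recorded back onto the truth object.
    """
    rng = np.random.default_rng(config.seed + 1)
    all_genes = truth.variances.index.to_numpy()
    planted = np.array(sorted(truth.planted_genes()))
    null = np.array(sorted(set(all_genes) - set(planted)))
    collection = GeneSetCollection()
    for plan in config.panel_plan:
        n_overlap = round(plan.overlap_with_signatures * plan.size)
        n_null = plan.size - n_overlap
        if n_overlap > planted.size or n_null > null.size:
            raise ValueError(
                f"panel {plan.name!r}: requested overlap infeasible "
                f"({n_overlap} of {planted.size} planted, "
                f"{n_null} of {null.size} null)")
        members = np.concatenate([
            rng.choice(planted, size=n_overlap, replace=False),
            rng.choice(null, size=n_null, replace=False)])
        members = sorted(members.tolist())
        collection.add(plan.name, members,
                       f"synthetic marker panel (overlap {plan.overlap_with_signatures})")
        truth.panels[plan.name] = members
    return collection


def make_footprint(truth: PlantedTruth, contrast_label: str,
                   direction: str = "up", extra_fraction: float = 0.2,
                   seed: int = 0) -> set[str]:
    """An external-evidence gene list: planted genes plus unrelated extras.

    Emulates an independently derived expression footprint consumed as a
    plain gene list: it contains every planted gene of the requested
    contrast/direction plus ``extra_fraction`` as many null genes.
    """
    rng = np.random.default_rng(seed + 2)
    core = truth.genes(contrast_label, direction)
    null = np.array(sorted(set(truth.variances.index) - truth.planted_genes()))
    n_extra = round(extra_fraction * len(core))
    extras = rng.choice(null, size=min(n_extra, null.size), replace=False)
    return core | set(extras.tolist())


# ---------------------------------------------------------------------------
# Unstable (heterogeneous) contrast scenario
# ---------------------------------------------------------------------------

def simulate_unstable_contrast(n_genes: int = 2000, n_a: int = 20,
                               n_b: int = 10, n_planted: int = 1800,
                               effect_range: tuple[float, float] = (0.25, 2.5),
                               noise_prior: tuple[float, float] = (4.0, 0.05),
                               baseline_mean: float = 8.0,
                               baseline_sd: float = 1.5,
                               seed: int = 0
                               ) -> tuple[ExpressionMatrix, pd.DataFrame,
                                          GroupContrast]:
    """A contrast whose group A activates its signature incoherently.

    Models a transitional population in which each responsive gene is
    switched on to a different degree in each sample: planted gene g has
    a magnitude e_g (uniform over ``effect_range``) and a gene-specific
    coherence floor l_g ~ U(0, 1); its realised shift in group-A sample s
    is ``e_g * u_{g,s}`` with ``u_{g,s} ~ U(l_g, 1)``. Genes with a high
    floor behave almost homogeneously (detected in essentially every
    resampling draw) while low-floor genes are detected only when the
    draw happens to favour their responsive samples, so per-iteration
    detection probabilities form a continuum that accumulates densely
    just below 1. Under cumulative intersection this yields sustained
    attrition of the stable set — the contrast keeps losing genes instead
    of reaching a plateau, the diagnostic behaviour of a heterogeneous
    contrast.
    """
    if n_planted > n_genes:
        raise ValueError("n_planted exceeds n_genes")
    rng = np.random.default_rng(seed)
    gene_ids = np.array([f"G{i + 1:05d}" for i in range(n_genes)])
    d0, s0 = noise_prior
    variances = s0 * d0 / rng.chisquare(d0, size=n_genes)
    baselines = rng.normal(baseline_mean, baseline_sd, n_genes)
    planted_idx = rng.permutation(n_genes)[:n_planted]
    effects = rng.uniform(*effect_range, size=n_planted)
    floors = rng.uniform(0.0, 1.0, size=n_planted)

    samples = [f"HET_s{i + 1:02d}" for i in range(n_a)] + \
              [f"REF_s{i + 1:02d}" for i in range(n_b)]
    values = np.empty((n_genes, n_a + n_b))
    noise = rng.normal(0.0, 1.0, size=values.shape) * np.sqrt(variances)[:, None]
    values[:] = baselines[:, None] + noise
    # per-gene per-sample response level in group A only
    response = rng.uniform(floors[:, None], 1.0, size=(n_planted, n_a))
    values[planted_idx, :n_a] += effects[:, None] * response
    mat = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=samples))
    ann = pd.DataFrame(
        [{"sample_id": s, "cell_type": "HET" if s.startswith("HET") else "REF",
          "lineage": MESENCHYMAL, "tissue": "synthetic", "batch": "B1"}
         for s in samples])
    contrast = GroupContrast("HET_vs_REF", samples[:n_a], samples[n_a:])
    return mat, ann, contrast


def simulate_coexpression_module(n_module: int = 20, n_background: int = 200,
                                 n_samples: int = 50, within_r: float = 0.98,
                                 seed: int = 0
                                 ) -> tuple[ExpressionMatrix, list[str]]:
    """A gene set driven by one latent factor inside independent noise.

    Module genes are ``sqrt(within_r) * f + sqrt(1 - within_r) * eps`` for
    a shared per-sample factor f, so the expected pairwise Pearson
    correlation inside the module is ``within_r``; background genes are
    independent standard normals. Returns the matrix and the module gene
    ids.
    """
    if not 0 < within_r < 1:
        raise ValueError("within_r must be in (0, 1)")
    rng = np.random.default_rng(seed)
    factor = rng.normal(size=n_samples)
    module = (np.sqrt(within_r) * factor
              + np.sqrt(1.0 - within_r) * rng.normal(size=(n_module, n_samples)))
    background = rng.normal(size=(n_background, n_samples))
    gene_ids = ([f"MOD{i + 1:04d}" for i in range(n_module)]
                + [f"BG{i + 1:05d}" for i in range(n_background)])
    samples = [f"s{j + 1:03d}" for j in range(n_samples)]
    mat = ExpressionMatrix(pd.DataFrame(np.vstack([module, background]),
                                        index=gene_ids, columns=samples))
    return mat, gene_ids[:n_module]


# ---------------------------------------------------------------------------
# Growth records
# ---------------------------------------------------------------------------

@dataclass
class GrowthSimConfig:
    """Per-class true doubling times and sampling noise for growth records."""

    class_pdts: tuple[tuple[str, float], ...] = (
        ("BM-MSC", 45.0), ("AD-MSC", 55.0), ("PL-MSC", 35.0), ("FIB", 30.0))
    n_passages: int = 6
    cultures_per_class: int = 4
    noise_sd: float = 0.10           # sd of log-normal jitter on the true PDT
    t_expan: float = 120.0           # hours per passage
    q1: float = 2.0e5                # cells seeded per passage
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.class_pdts:
            raise ValueError("need >= 1 class")
        if self.n_passages < 2:
            raise ValueError("need >= 2 passages")
        if any(pdt <= 0 for _, pdt in self.class_pdts):
            raise ValueError("true PDTs must be positive")


def simulate_growth_records(config: GrowthSimConfig) -> list[GrowthRecord]:
    """Growth records whose derived PDTs scatter around class-true values.

    Each record's realised doubling time is ``true_pdt * exp(eps)`` with
    ``eps ~ N(0, noise_sd^2)``; harvested counts follow exponential growth
    over ``t_expan`` hours, so Q2 > Q1 always holds and ``noise_sd = 0``
    reproduces the true PDT exactly.
    """
    rng = np.random.default_rng(config.seed)
    records: list[GrowthRecord] = []
    for cls, true_pdt in config.class_pdts:
        for culture in range(1, config.cultures_per_class + 1):
            for passage in range(1, config.n_passages + 1):
                realised = true_pdt * float(np.exp(
                    rng.normal(0.0, config.noise_sd))) if config.noise_sd > 0 \
                    else true_pdt
                q2 = config.q1 * 2.0 ** (config.t_expan / realised)
                records.append(GrowthRecord(
                    culture_id=f"{cls}_c{culture}", cell_class=cls,
                    passage=passage, q1=config.q1, q2=q2,
                    t_expan=config.t_expan))
    return records


# ---------------------------------------------------------------------------
# On-disk emission
# ---------------------------------------------------------------------------

def write_truth(truth: PlantedTruth, path) -> None:
    out = truth.assignments.copy()
    out["variance"] = out["gene_id"].map(truth.variances)
    out.to_csv(path, sep="\t", index=False)


def write_dataset(outdir, mat: ExpressionMatrix, ann: pd.DataFrame,
                  truth: PlantedTruth,
                  panels: GeneSetCollection | None = None) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"expression": outdir / "expression.tsv",
             "annotation": outdir / "annotation.tsv",
             "truth": outdir / "truth.tsv"}
    write_matrix(mat, paths["expression"])
    write_annotation(ann, paths["annotation"])
    write_truth(truth, paths["truth"])
    if panels is not None:
        paths["panels"] = outdir / "panels.gmt"
        write_gmt(panels, paths["panels"])
    return paths
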