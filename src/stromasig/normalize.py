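"""Frozen-reference normalization and variance filtering.

Multi-series compendia carry per-series (batch) technical offsets. Rather
than refitting a normalization model on the full compendium every time an
array is added, a reference is *frozen* once from a balanced subsample of
the batches: a target quantile vector (the per-rank mean of sorted sample
vectors) plus one per-gene offset vector per batch (the mean residual of
that batch's quantile-normalized arrays around the across-batch per-gene
mean). Applying the reference to any array is then a pure lookup: replace
the array's values by the reference quantiles at its value ranks, and
subtract the array's batch offset vector.

This is a gene-level simplification of frozen-parameter array
normalization: it keeps the "balanced subsets, frozen vectors" structure
while operating on summarised gene expression rather than probe-level data.

The module also provides the variance filter used before pattern
clustering (keep the top fraction of genes by cross-sample variance).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import ExpressionMatrix, _FLOAT_FORMAT

logger = logging.getLogger("stromasig")


@dataclass
class FrozenReference:
    """Frozen quantile target plus per-batch per-gene additive offsets."""

    gene_ids: list[str]
    reference_quantiles: np.ndarray  # sorted, length n_genes
    batch_offsets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        q = np.asarray(self.reference_quantiles, dtype=float)
        if np.any(np.diff(q) < 0):
            raise ValueError("reference_quantiles must be sorted non-decreasing")
        if len(self.gene_ids) != q.size:
            raise ValueError("gene_ids and reference_quantiles length mismatch")
        self.reference_quantiles = q
        for b, off in self.batch_offsets.items():
            off = np.asarray(off, dtype=float)
            if off.size != q.size:
                raise ValueError(f"offset vector for batch {b!r} has wrong length")
            self.batch_offsets[b] = off

    @property
    def batches(self) -> list[str]:
        return list(self.batch_offsets)


def build_frozen_reference(mats: Sequence[tuple[ExpressionMatrix, str]],
                           per_batch_n: int = 3,
                           seed: int = 0) -> FrozenReference:
    """Freeze a normalization reference from a balanced batch subsample.

    Parameters
    ----------
    mats:
        ``(matrix, batch_id)`` pairs; matrices must share gene ids. The
        same batch id may appear several times (its samples are pooled).
    per_batch_n:
        Number of arrays drawn (without replacement, seeded) from each
        batch; every batch must have at least this many samples.
    """
    if per_batch_n < 1:
        raise ValueError("per_batch_n must be >= 1")
    by_batch: dict[str, list[pd.DataFrame]] = {}
    gene_ids: list[str] | None = None
    for mat, batch in mats:
        if gene_ids is None:
            gene_ids = mat.gene_ids
        elif mat.gene_ids != gene_ids:
            if set(mat.gene_ids) != set(gene_ids):
                raise ValueError("matrices must share gene ids")
            mat = ExpressionMatrix(mat.data.loc[gene_ids])
        by_batch.setdefault(batch, []).append(mat.data)
    if gene_ids is None or len(by_batch) < 2:
        raise ValueError("need >= 2 batches to freeze a reference")

    rng = np.random.default_rng(seed)
    chosen: dict[str, np.ndarray] = {}
    for batch in sorted(by_batch):
        pooled = pd.concat(by_batch[batch], axis=1)
        if pooled.shape[1] < per_batch_n:
            raise ValueError(
                f"batch {batch!r} has {pooled.shape[1]} samples, "
                f"fewer than per_batch_n={per_batch_n}")
        cols = rng.choice(pooled.shape[1], size=per_batch_n, replace=False)
        chosen[batch] = pooled.iloc[:, sorted(cols)].to_numpy()

    # target quantiles: per-rank mean of the sorted balanced subsample
    stacked = np.column_stack([v for b in sorted(chosen) for v in chosen[b].T])
    reference = np.sort(stacked, axis=0).mean(axis=1)

    # per-batch offsets: residual of quantile-normalized batch means around
    # the (balanced) across-batch per-gene mean
    batch_means: dict[str, np.ndarray] = {}
    for batch, arr in chosen.items():
        normed = np.column_stack(
            [_quantile_transform(arr[:, j], reference) for j in range(arr.shape[1])])
        batch_means[batch] = normed.mean(axis=1)
    grand = np.mean([batch_means[b] for b in sorted(batch_means)], axis=0)
    offsets = {b: batch_means[b] - grand for b in sorted(batch_means)}
    return FrozenReference(gene_ids=list(gene_ids),
                           reference_quantiles=reference,
                           batch_offsets=offsets)


def _quantile_transform(x: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Replace values by reference quantiles at their ranks.

    Ties receive the mean of the reference values at the tied rank
    positions; untied values receive the reference value at their rank.
    """
    order = np.argsort(x, kind="mergesort")
    out = np.empty_like(reference)
    xs = x[order]
    i = 0
    n = x.size
    while i < n:
        j = i
        while j + 1 < n and xs[j + 1] == xs[i]:
            j += 1
        out[order[i:j + 1]] = reference[i:j + 1].mean()
        i = j + 1
    return out


def apply_frozen_normalization(mat: ExpressionMatrix,
                               ref: FrozenReference,
                               sample_batches: Mapping[str, str]
                               ) -> ExpressionMatrix:
    """Normalize every sample against a frozen reference.

    Each sample's values are replaced by the reference quantiles at the
    sample's value ranks, then the sample's batch offset vector is
    subtracted. Samples whose batch is unknown to the reference get the
    quantile step only (logged).
    """
    if mat.gene_ids != ref.gene_ids:
        if set(mat.gene_ids) != set(ref.gene_ids):
            raise ValueError("matrix gene ids do not match frozen reference")
        mat = ExpressionMatrix(mat.data.loc[ref.gene_ids])
    out = {}
    n_unknown = 0
    for sample in mat.sample_ids:
        x = mat.data[sample].to_numpy()
        normed = _quantile_transform(x, ref.reference_quantiles)
        batch = sample_batches.get(sample)
        if batch in ref.batch_offsets:
            normed = normed - ref.batch_offsets[batch]
        else:
            n_unknown += 1
        out[sample] = normed
    if n_unknown:
        logger.warning("apply_frozen_normalization: %d samples with unknown "
                       "batch got the quantile step only", n_unknown)
    return ExpressionMatrix(pd.DataFrame(out, index=ref.gene_ids))


def variance_filter(mat: ExpressionMatrix,
                    keep_fraction: float) -> ExpressionMatrix:
    """Keep the top ``ceil(keep_fraction * n_genes)`` genes by variance.

    Per-gene variance is the population variance across samples (divisor
    n); ties are broken by gene-id lexicographic order. The kept genes are
    returned in their original row order.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    variances = mat.data.var(axis=1, ddof=0)
    k = math.ceil(keep_fraction * mat.shape[0])
    ranked = sorted(mat.gene_ids, key=lambda g: (-variances[g], g))
    keep = set(ranked[:k])
    kept_in_order = [g for g in mat.gene_ids if g in keep]
    return ExpressionMatrix(mat.data.loc[kept_in_order])


def batch_variance_fraction(mat: ExpressionMatrix,
                            sample_batches: Mapping[str, str]) -> float:
    """Fraction of total per-gene variance attributable to batch.

    One-way between/within decomposition per gene, averaged over genes:
    between-batch sum of squares over total sum of squares. Used to verify
    that frozen-reference normalization removes batch structure.
    """
    batches = pd.Series({s: sample_batches[s] for s in mat.sample_ids})
    x = mat.data
    grand = x.mean(axis=1)
    ss_total = ((x.sub(grand, axis=0)) ** 2).sum(axis=1)
    ss_between = pd.Series(0.0, index=x.index)
    for batch, cols in batches.groupby(batches).groups.items():
        sub = x[list(cols)]
        ss_between += len(cols) * (sub.mean(axis=1) - grand) ** 2
    valid = ss_total > 0
    return float((ss_between[valid] / ss_total[valid]).mean())


# ---------------------------------------------------------------------------
# Serialization: TSV bundle (quantiles + one offsets file per batch) + YAML index
# ---------------------------------------------------------------------------

def save_frozen_reference(ref: FrozenReference, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"gene_id": ref.gene_ids,
                  "reference_quantile": ref.reference_quantiles}
                 ).to_csv(directory / "reference_quantiles.tsv", sep="\t",
                          index=False, float_format=_FLOAT_FORMAT)
    index = {"quantiles": "reference_quantiles.tsv", "batches": {}}
    for batch, off in ref.batch_offsets.items():
        fname = f"offsets_{batch}.tsv"
        pd.DataFrame({"gene_id": ref.gene_ids, "offset": off}
                     ).to_csv(directory / fname, sep="\t", index=False,
                              float_format=_FLOAT_FORMAT)
        index["batches"][batch] = fname
    with open(directory / "frozen_reference.yaml", "w") as fh:
        yaml.safe_dump(index, fh)


def load_frozen_reference(directory) -> FrozenReference:
    directory = Path(directory)
    with open(directory / "frozen_reference.yaml") as fh:
        index = yaml.safe_load(fh)
    qdf = pd.read_csv(directory / index["quantiles"], sep="\t")
    offsets = {}
    for batch, fname in index["batches"].items():
        odf = pd.read_csv(directory / fname, sep="\t")
        offsets[str(batch)] = odf["offset"].to_numpy()
    return FrozenReference(gene_ids=qdf["gene_id"].astype(str).tolist(),
                           reference_quantiles=qdf["reference_quantile"].to_numpy(),
                           batch_offsets=offsets)
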