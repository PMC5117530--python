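"""Stability resampling of differential-expression contrasts.

Differential expression from a single fit of a heterogeneous compendium is
fragile: which genes pass the FDR cutoff depends on which samples were
recruited. The protocol implemented here resamples each two-group contrast
many times — drawing a small balanced subset (default 7 vs 7) of columns
with replacement per iteration, rerunning the full moderated pipeline
(pooled statistics, per-iteration hyperparameter estimation, moderated t,
BH-FDR, fdr < alpha calls) — and keeps only the genes that are significant
with a consistent direction in *every* iteration. The cumulative stable
sets can only shrink, so they converge; iteration stops once their sizes
have been flat for a patience window (the "plateau") or at a hard cap.
Each gene is also ranked by FDR in every iteration (over all genes, ties
averaged) and the per-gene median rank over iterations is reported for the
stable genes.

Contrasts whose groups are internally heterogeneous — e.g. a group mixing
cells at different stages of commitment — never plateau: their stable sets
keep eroding, which is itself the diagnostic output of the protocol.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .diffexpr import (GroupContrast, bh_adjust, estimate_prior,
                       group_stats, moderated_test, rank_by_fdr)
from .io_formats import ExpressionMatrix, _FLOAT_FORMAT

logger = logging.getLogger("stromasig")


@dataclass
class ResamplingConfig:
    """Knobs of the resampling protocol.

    k_per_group:
        Columns drawn per group per iteration (with replacement).
    alpha:
        FDR cutoff for a per-iteration call.
    max_iters / min_iters / patience:
        Hard iteration cap; minimum iterations before the plateau test is
        consulted; number of trailing iterations whose cumulative
        stable-set sizes must all be equal for a plateau.
    """

    k_per_group: int = 7
    alpha: float = 0.05
    max_iters: int = 200
    min_iters: int = 50
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_per_group < 2:
            raise ValueError("k_per_group must be >= 2")
        if not 1 <= self.min_iters <= self.max_iters:
            raise ValueError("need 1 <= min_iters <= max_iters")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class StabilityResult:
    """Outcome of resampling one contrast."""

    contrast: str
    stable_up: set[str]
    stable_down: set[str]
    call_frequency: pd.DataFrame   # index gene, columns up/down, values in [0,1]
    median_rank: pd.Series         # stable genes only
    trace: pd.DataFrame            # iteration, n_de_up, n_de_down,
                                   # n_stable_up, n_stable_down
    iterations_run: int
    plateaued: bool
    config: ResamplingConfig


def plateau_reached(trace: pd.DataFrame, patience: int,
                    min_iters: int) -> bool:
    """True iff the cumulative stable-set sizes have gone flat.

    Requires at least ``min_iters`` executed iterations and that the last
    ``patience`` values of both cumulative stable-set sizes are all equal.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    if len(trace) < max(min_iters, patience):
        return False
    tail = trace.iloc[-patience:]
    return (tail["n_stable_up"].nunique() == 1
            and tail["n_stable_down"].nunique() == 1)


def aggregate_ranks(rank_table: pd.DataFrame,
                    stable_genes: Sequence[str]) -> pd.Series:
    """Per-gene median rank over all executed iterations (true median)."""
    missing = [g for g in stable_genes if g not in rank_table.columns]
    if missing:
        raise KeyError(f"genes absent from rank table: {missing[:5]}")
    return rank_table[list(stable_genes)].median(axis=0)


def resample_contrast(mat: ExpressionMatrix, ann: pd.DataFrame,
                      contrast: GroupContrast,
                      config: ResamplingConfig | None = None
                      ) -> StabilityResult:
    """Run the full stability protocol for one contrast.

    Per iteration: draw ``k_per_group`` columns per group uniformly with
    replacement from a seeded stream, run the moderated pipeline, call
    fdr < alpha, intersect cumulatively, and rank all genes by FDR. Stops
    at the plateau or at ``max_iters``.
    """
    config = config or ResamplingConfig()
    for side, members in (("A", contrast.group_a), ("B", contrast.group_b)):
        present = [s for s in members if s in set(ann["sample_id"])]
        if len(set(present)) < 2:
            raise ValueError(
                f"contrast {contrast.name!r}: group {side} needs >= 2 "
                "distinct annotated samples")
    rng = np.random.default_rng(config.seed)
    genes = mat.gene_ids
    n_genes = len(genes)
    k = config.k_per_group

    stable_up: set[str] | None = None
    stable_down: set[str] | None = None
    up_counts = pd.Series(0.0, index=genes)
    down_counts = pd.Series(0.0, index=genes)
    ranks: list[np.ndarray] = []
    trace_rows: list[dict] = []
    plateaued = False

    for iteration in range(1, config.max_iters + 1):
        cols_a = list(rng.choice(contrast.group_a, size=k, replace=True))
        cols_b = list(rng.choice(contrast.group_b, size=k, replace=True))
        sub = GroupContrast(contrast.name, cols_a, cols_b)
        gstats = group_stats(mat, sub)
        prior = estimate_prior(gstats.s2, gstats.df_resid)
        _, p = moderated_test(gstats, prior)
        fdr = bh_adjust(p)
        sig = fdr < config.alpha
        up = set(np.asarray(genes)[sig & (gstats.logfc > 0)])
        down = set(np.asarray(genes)[sig & (gstats.logfc < 0)])
        ranks.append(rank_by_fdr(fdr))
        up_counts[list(up)] += 1
        down_counts[list(down)] += 1
        stable_up = up if stable_up is None else stable_up & up
        stable_down = down if stable_down is None else stable_down & down
        trace_rows.append({"iteration": iteration,
                           "n_de_up": len(up), "n_de_down": len(down),
                           "n_stable_up": len(stable_up),
                           "n_stable_down": len(stable_down)})
        trace = pd.DataFrame(trace_rows)
        if iteration >= config.min_iters and plateau_reached(
                trace, config.patience, config.min_iters):
            plateaued = True
            break

    trace = pd.DataFrame(trace_rows)
    iterations_run = len(trace_rows)
    rank_table = pd.DataFrame(np.vstack(ranks), columns=genes)
    call_frequency = pd.DataFrame({"up": up_counts / iterations_run,
                                   "down": down_counts / iterations_run})
    stable = sorted(stable_up | stable_down)
    median_rank = (aggregate_ranks(rank_table, stable)
                   if stable else pd.Series(dtype=float))
    if not plateaued:
        logger.warning("contrast %r did not plateau within %d iterations "
                       "(unstable contrast?)", contrast.name, iterations_run)
    return StabilityResult(contrast=contrast.name,
                           stable_up=stable_up, stable_down=stable_down,
                           call_frequency=call_frequency,
                           median_rank=median_rank, trace=trace,
                           iterations_run=iterations_run,
                           plateaued=plateaued, config=config)


def de_count_matrix(results: Mapping[tuple[str, str], StabilityResult]
                    ) -> pd.DataFrame:
    """Pairwise DE-count distance matrix from per-pair stability results.

    ``results[(i, j)]`` is the stability result of contrast i vs j (A - B
    orientation); entry (i, j) of the returned matrix is the number of
    stable up-regulated genes in i against j. The matrix is asymmetric:
    entry (i, j) counts what entry (j, i) sees as down-regulation.
    """
    classes = sorted({c for pair in results for c in pair})
    for i in classes:
        for j in classes:
            if i != j and (i, j) not in results:
                raise KeyError(f"missing stability result for pair ({i}, {j})")
    out = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for (i, j), res in results.items():
        out.loc[i, j] = len(res.stable_up)
    return out


# ---------------------------------------------------------------------------
# Serialization: stable-gene table + trace table + YAML run manifest
# ---------------------------------------------------------------------------

def save_stability_result(result: StabilityResult, directory,
                          prefix: str | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prefix = prefix or result.contrast
    rows = []
    for direction, members in (("up", result.stable_up),
                               ("down", result.stable_down)):
        for gene in sorted(members):
            rows.append({"gene_id": gene, "direction": direction,
                         "call_frequency": result.call_frequency.loc[gene, direction],
                         "median_rank": result.median_rank[gene]})
    pd.DataFrame(rows, columns=["gene_id", "direction", "call_frequency",
                                "median_rank"]
                 ).to_csv(directory / f"{prefix}_stable.tsv", sep="\t",
                          index=False, float_format=_FLOAT_FORMAT)
    result.trace.to_csv(directory / f"{prefix}_trace.tsv", sep="\t",
                        index=False)
    manifest = {"contrast": result.contrast,
                "iterations_run": int(result.iterations_run),
                "plateaued": bool(result.plateaued),
                "n_stable_up": len(result.stable_up),
                "n_stable_down": len(result.stable_down),
                "config": asdict(result.config)}
    with open(directory / f"{prefix}_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
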