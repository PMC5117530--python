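"""Two-group moderated differential expression.

The statistical engine behind the resampling protocol: an empirical-Bayes
moderated t-test for two-group contrasts, in the standard hierarchical
formulation. Per gene g with pooled within-group variance s_g^2 on d_g
residual degrees of freedom, the gene-level variances are modelled as
draws from a scaled inverse-chi-square prior with hyperparameters
(d0, s0^2). The posterior variance

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

shrinks each gene's variance toward the prior, and

    t_g = logFC_g / sqrt(s_tilde_g^2 * (1/nA + 1/nB))

is referred to a t distribution on d0 + d_g degrees of freedom. The
hyperparameters are estimated by method of moments on z = log(s^2):
under the model Var(z) = trigamma(d_g/2) + trigamma(d0/2) and
E(z) = log(s0^2) + digamma(d_g/2) - log(d_g/2) - digamma(d0/2) + log(d0/2),
so d0 solves trigamma(d0/2) = Var(z) - trigamma(d_g/2) (d0 = +inf when the
observed spread does not exceed the sampling spread) and s0^2 follows from
the mean equation.

Significance is controlled with Benjamini-Hochberg FDR; a gene is called
differentially expressed when fdr < alpha, with no fold-change cutoff.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, _FLOAT_FORMAT

logger = logging.getLogger("stromasig")


@dataclass
class GroupContrast:
    """A named two-group comparison, oriented A - B (positive logFC = up in A)."""

    name: str
    group_a: list[str]
    group_b: list[str]

    def __post_init__(self) -> None:
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError(f"contrast {self.name!r}: each side needs >= 2 columns")
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"contrast {self.name!r}: groups share sample labels")


def contrast_from_annotation(ann: pd.DataFrame, name_a: str, name_b: str,
                             column: str = "cell_type",
                             label: str | None = None) -> GroupContrast:
    """Build a contrast from annotation rows matching two class labels.

    ``name_a``/``name_b`` may name a value of ``column`` or of the
    ``lineage`` column (so whole-lineage contrasts work the same way).
    """
    def _members(name: str) -> list[str]:
        mask = ann[column] == name
        if not mask.any() and "lineage" in ann.columns:
            mask = ann["lineage"] == name
        ids = ann.loc[mask, "sample_id"].tolist()
        if not ids:
            raise ValueError(f"no samples match group {name!r}")
        return ids

    return GroupContrast(name=label or f"{name_a}_vs_{name_b}",
                         group_a=_members(name_a), group_b=_members(name_b))


@dataclass
class GroupStats:
    """Per-gene two-group summary statistics."""

    gene_ids: list[str]
    logfc: np.ndarray        # meanA - meanB
    s2: np.ndarray           # pooled within-group variance
    df_resid: int            # nA + nB - 2
    n_a: int
    n_b: int


@dataclass
class Prior:
    """Empirical-Bayes variance prior: scaled inverse-chi-square(d0, s0_sq)."""

    d0: float
    s0_sq: float


@dataclass
class DEResult:
    """Full per-gene differential-expression table for one contrast."""

    contrast: str
    table: pd.DataFrame      # columns: logfc, s2, t, p, fdr, rank
    prior: Prior
    df_resid: int
    n_a: int = 0
    n_b: int = 0

    @property
    def genes(self) -> list[str]:
        return self.table.index.tolist()


def group_stats(mat: ExpressionMatrix, contrast: GroupContrast) -> GroupStats:
    """Per-gene logFC, pooled variance and residual df for a two-group contrast.

    Group member lists may contain repeated sample ids (columns drawn with
    replacement during resampling); repeats contribute as independent
    columns and the residual df is computed from the drawn counts.
    """
    missing = [s for s in contrast.group_a + contrast.group_b
               if s not in mat.data.columns]
    if missing:
        raise KeyError(f"contrast columns absent from matrix: {missing[:5]}")
    a = mat.data[contrast.group_a].to_numpy()
    b = mat.data[contrast.group_b].to_numpy()
    n_a, n_b = a.shape[1], b.shape[1]
    df_resid = n_a + n_b - 2
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    ss_a = ((a - mean_a[:, None]) ** 2).sum(axis=1)
    ss_b = ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = (ss_a + ss_b) / df_resid
    return GroupStats(gene_ids=mat.gene_ids, logfc=mean_a - mean_b, s2=s2,
                      df_resid=df_resid, n_a=n_a, n_b=n_b)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/x scale)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df_resid: int,
                   min_genes: int = 10) -> Prior:
    """Method-of-moments hyperparameter estimation on log variances.

    Genes with zero sample variance carry no information about the prior
    on the log scale and are excluded from the moment equations; at least
    ``min_genes`` positive variances are required.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("all gene variances are zero")
    if positive.size < min_genes:
        raise ValueError(
            f"need >= {min_genes} genes with positive variance, "
            f"got {positive.size}")
    if np.all(positive == positive[0]):
        # degenerate zero-spread limit: no information about d0 beyond
        # "no excess spread"; report the common value itself
        return Prior(d0=math.inf, s0_sq=float(positive[0]))
    z = np.log(positive)
    half_d = df_resid / 2.0
    e_z = z.mean() - special.digamma(half_d) + math.log(half_d)
    var_z = z.var(ddof=1)
    excess = var_z - special.polygamma(1, half_d)
    if excess <= 0:
        return Prior(d0=math.inf, s0_sq=float(math.exp(e_z)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(e_z + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return Prior(d0=float(d0), s0_sq=float(s0_sq))


def moderated_test(gstats: GroupStats, prior: Prior
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t statistics and two-sided p-values.

    d0 = 0 degenerates to the ordinary pooled two-sample t; d0 = +inf sets
    every posterior variance to s0_sq (normal reference distribution).
    """
    d0, s0 = prior.d0, prior.s0_sq
    dg = gstats.df_resid
    if math.isinf(d0):
        s2_post = np.full_like(gstats.s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + dg * gstats.s2) / (d0 + dg)
        df_total = d0 + dg
    scale2 = s2_post * (1.0 / gstats.n_a + 1.0 / gstats.n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = gstats.logfc / np.sqrt(scale2)
    zero_scale = scale2 == 0
    if np.any(zero_scale):
        warnings.warn("zero posterior variance for some genes; their p-values "
                      "are set to the smallest representable positive float")
        t = np.where(zero_scale, np.sign(gstats.logfc) * np.inf, t)
        t = np.where(zero_scale & (gstats.logfc == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return t, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_by_fdr(fdr: np.ndarray) -> np.ndarray:
    """Rank genes by FDR ascending, ties averaged (1 = most significant)."""
    return stats.rankdata(fdr, method="average")


def de_analysis(mat: ExpressionMatrix, contrast: GroupContrast,
                prior: Prior | None = None) -> DEResult:
    """Run the full moderated pipeline for one contrast.

    Hyperparameters are estimated from this contrast's own pooled
    variances unless an explicit prior is supplied.
    """
    gstats = group_stats(mat, contrast)
    if prior is None:
        prior = estimate_prior(gstats.s2, gstats.df_resid)
    t, p = moderated_test(gstats, prior)
    fdr = bh_adjust(p)
    table = pd.DataFrame({"logfc": gstats.logfc, "s2": gstats.s2,
                          "t": t, "p": p, "fdr": fdr,
                          "rank": rank_by_fdr(fdr)},
                         index=pd.Index(gstats.gene_ids, name="gene_id"))
    return DEResult(contrast=contrast.name, table=table, prior=prior,
                    df_resid=gstats.df_resid, n_a=gstats.n_a, n_b=gstats.n_b)


def call_de(result: DEResult, alpha: float = 0.05
            ) -> tuple[set[str], set[str]]:
    """Split significant genes (fdr < alpha, strict) by logFC sign."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    tab = result.table
    sig = tab["fdr"] < alpha
    up = set(tab.index[sig & (tab["logfc"] > 0)])
    down = set(tab.index[sig & (tab["logfc"] < 0)])
    return up, down


def write_de_result(result: DEResult, path) -> None:
    result.table.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT)
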