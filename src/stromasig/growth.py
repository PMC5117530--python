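"""Population doubling times and their nonparametric comparison.

A culture seeded with Q1 cells and harvested with Q2 cells after TExpan
hours has undergone log2(Q2/Q1) doublings, so its population doubling
time is

    PDT = TExpan * log(2) / log(Q2 / Q1)    [hours]

(the ratio of logs makes the value base-invariant). Doubling times of two
cell classes are compared with the two-sided Wilcoxon rank-sum test: exact
by enumeration of group assignments for small samples (nA + nB <= 12,
mid-ranked ties), normal approximation with continuity and tie correction
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GrowthRecord:
    """One passage of one culture: seeded/harvested counts and expansion time."""

    culture_id: str
    cell_class: str
    passage: int
    q1: float          # cells seeded
    q2: float          # cells harvested
    t_expan: float     # expansion time, hours

    def __post_init__(self) -> None:
        if self.q1 <= 0 or self.q2 <= 0:
            raise ValueError("cell counts must be positive")
        if self.t_expan <= 0:
            raise ValueError("expansion time must be positive")


def doubling_time(record: GrowthRecord) -> float:
    """Population doubling time in hours; requires positive growth (Q2 > Q1)."""
    if record.q2 <= record.q1:
        raise ValueError(
            f"non-positive growth for culture {record.culture_id!r}: "
            f"Q2={record.q2} <= Q1={record.q1}")
    return record.t_expan * math.log(2.0) / math.log(record.q2 / record.q1)


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def compare_growth(pdts_a: Sequence[float], pdts_b: Sequence[float],
                   exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two PDT samples.

    Returns ``(W, p)`` where W is the rank sum of the first group
    (mid-ranked ties). Exact p by enumeration of all group assignments
    when nA + nB <= ``exact_max_n``; otherwise the normal approximation
    with continuity correction and tie-corrected variance.
    """
    a = np.asarray(pdts_a, dtype=float)
    b = np.asarray(pdts_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 values")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    w = float(ranks[:n_a].sum())
    mu = n_a * (n + 1) / 2.0

    if n <= exact_max_n:
        # enumerate all C(n, n_a) assignments of ranks to group A
        sums = [sum(ranks[list(idx)]) for idx in combinations(range(n), n_a)]
        sums = np.asarray(sums)
        p_low = np.mean(sums <= w + 1e-9)
        p_high = np.mean(sums >= w - 1e-9)
        p = min(1.0, 2.0 * min(p_low, p_high))
        return w, float(p)

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return w, 1.0
    diff = w - mu
    z = (diff - math.copysign(0.5, diff)) / math.sqrt(sigma2) if diff != 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return w, float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Records TSV
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = ["culture_id", "cell_class", "passage", "q1", "q2", "t_expan"]


def write_growth_records(records: Sequence[GrowthRecord], path) -> None:
    pd.DataFrame([record.__dict__ for record in records]
                 ).to_csv(path, sep="\t", index=False)


def read_growth_records(path) -> list[GrowthRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"growth table missing columns: {missing}")
    return [GrowthRecord(culture_id=str(r.culture_id),
                         cell_class=str(r.cell_class), passage=int(r.passage),
                         q1=float(r.q1), q2=float(r.q2),
                         t_expan=float(r.t_expan))
            for r in df.itertuples()]


def pdt_table(records: Sequence[GrowthRecord]) -> pd.DataFrame:
    """Per-record PDT table (culture, class, passage, pdt_hours)."""
    return pd.DataFrame(
        [{"culture_id": r.culture_id, "cell_class": r.cell_class,
          "passage": r.passage, "pdt_hours": doubling_time(r)}
         for r in records])
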