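"""Clonal lineage diversity and barcode-group enrichment shifts.

The lineage diversity index is the Simpson-type quantity 1 - sum_i p_i^2,
where p_i is the relative abundance of barcode group (lineage) i.  It is 0
when a single clone dominates completely and reaches its maximum, 1 - 1/n,
when all n groups are equally abundant; the scaled index divides by that
maximum so trajectories with different group counts are comparable.

`enrichment_shift_test` asks whether any barcode group changed frequency
between two timepoints (e.g. vehicle vs drug) beyond sampling noise: a
Fisher exact test per group on the two-timepoint count table, with
Benjamini-Hochberg correction across groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AbundanceVector",
    "normalize_abundance",
    "diversity_index",
    "scaled_diversity_index",
    "enrichment_shift_test",
    "clonal_expansion_space",
]


@dataclass
class AbundanceVector:
    """Relative abundances p_i over barcode groups (sum to 1)."""

    groups: list[str]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if len(self.groups) != self.p.size or self.p.size < 1:
            raise ValueError("groups and p must be equal-length and non-empty")
        if (self.p < 0).any():
            raise ValueError("abundances must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")

    @property
    def n(self) -> int:
        return self.p.size


def normalize_abundance(counts: Mapping[str, float] | pd.Series) -> AbundanceVector:
    """Turn per-group counts into relative abundances p_i = c_i / sum(c)."""
    s = pd.Series(counts, dtype=float)
    total = s.sum()
    if total <= 0:
        raise ValueError("at least one positive count required")
    return AbundanceVector(groups=[str(g) for g in s.index], p=(s / total).to_numpy())


def diversity_index(v: AbundanceVector) -> float:
    """Lineage diversity index 1 - sum_i p_i^2.

    Zero iff one group carries all abundance; maximal (1 - 1/n) iff all
    groups are equally abundant.
    """
    return float(1.0 - np.sum(v.p**2))


def scaled_diversity_index(v: AbundanceVector) -> float:
    """Diversity index scaled by its maximum 1 - 1/n for n groups.

    Requires n >= 2: with a single group the maximum is 0 and the ratio is
    undefined.
    """
    if v.n < 2:
        raise ValueError("scaled index undefined for a single group")
    return diversity_index(v) / (1.0 - 1.0 / v.n)


def enrichment_shift_test(
    counts_t0: Mapping[str, int] | pd.Series,
    counts_t1: Mapping[str, int] | pd.Series,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, bool]:
    """Per-group Fisher exact test of frequency change between timepoints.

    Groups absent at one timepoint enter with count 0 (the union universe):
    disappearance of a lineage is itself a shift worth detecting.  Returns
    ``(table, enriched)`` where the table holds per-group counts, odds
    ratio, p and BH q, and ``enriched`` is True iff any q <= alpha.
    """
    s0 = pd.Series(counts_t0, dtype=np.int64)
    s1 = pd.Series(counts_t1, dtype=np.int64)
    universe = s0.index.union(s1.index)
    s0 = s0.reindex(universe, fill_value=0)
    s1 = s1.reindex(universe, fill_value=0)
    n0, n1 = int(s0.sum()), int(s1.sum())
    if n0 < 1 or n1 < 1:
        raise ValueError("each timepoint needs at least one read")
    pvals = np.empty(len(universe))
    odds = np.empty(len(universe))
    for i, g in enumerate(universe):
        table = np.array([[s0[g], n0 - s0[g]], [s1[g], n1 - s1[g]]])
        odds[i], pvals[i] = stats.fisher_exact(table)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "count_t0": s0.to_numpy(),
            "count_t1": s1.to_numpy(),
            "freq_t0": s0.to_numpy() / n0,
            "freq_t1": s1.to_numpy() / n1,
            "odds_ratio": odds,
            "p": pvals,
            "q": qvals,
        },
        index=pd.Index(universe, name="group"),
    )
    return out, bool((qvals <= alpha).any())


def clonal_expansion_space(doublings: int) -> int:
    """Exact number of possible daughter cells after ``doublings`` doublings.

    ~112 doublings over a lineage-tracing timeline give 2**112 ≈ 5.2e33
    possible daughter cells — a search space of order 1e33.
    """
    if doublings < 0:
        raise ValueError("doublings must be >= 0")
    return 2**doublings
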