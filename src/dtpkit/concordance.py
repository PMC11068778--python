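"""Connectivity-style concordance screening of drug perturbation profiles.

Given a disease gene signature and a reference of drug-perturbation
differential-expression profiles (an L1000-level-4-like gene x perturbation
matrix), each profile is ranked from most up- to most down-regulated and
scored with a signed, rank-based statistic similar to the Kolmogorov-
Smirnov test statistic.  With the signature's (sorted, 1-based) positions
p_1 < ... < p_s among N ranked genes,

    a = max_j ( j/s - p_j/N )        (signature crowding the top)
    b = max_j ( p_j/N - (j-1)/s )    (signature crowding the bottom)
    score = a if a >= b else -b

A strongly negative score means the perturbation down-ranks the signature
genes — it opposes (reverses) the disease signature.  Empirical p-values
compare each score against a null of random gene sets of the same size;
Benjamini-Hochberg q-values are assigned across the screen and reversal
candidates are the significantly negative scorers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signature import GeneSignature, bh_adjust

__all__ = [
    "RankedProfile",
    "rank_profile",
    "ks_score",
    "null_scores",
    "concordance_screen",
    "select_reversers",
]


@dataclass
class RankedProfile:
    """A perturbation's genes ordered most up-regulated first."""

    genes: list[str]
    perturbation: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranking must be a bijection over the gene universe")

    @property
    def n(self) -> int:
        return len(self.genes)


def rank_profile(
    values: Mapping[str, float] | pd.Series, perturbation: str = ""
) -> RankedProfile:
    """Order genes by differential-expression value, descending.

    Ties are broken by gene identifier ascending, so the ranking is
    deterministic.  Duplicate gene identifiers are an error.
    """
    s = pd.Series(values, dtype=float)
    if s.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in profile")
    if s.isna().any():
        raise ValueError("profile contains missing values")
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return RankedProfile(genes=[str(g) for g in order], perturbation=perturbation)


def _score_from_positions(positions: np.ndarray, n: int) -> float:
    """Signed KS-like score from sorted 1-based signature positions."""
    s = positions.size
    j = np.arange(1, s + 1)
    a = float(np.max(j / s - positions / n))
    b = float(np.max(positions / n - (j - 1) / s))
    # ties (a == b, e.g. a top block with s = N-1) resolve to the positive
    # branch so block placements obey their closed forms on both ends;
    # the tolerance absorbs float rounding in j/s - p_j/N
    return a if a >= b - 1e-12 else -b


def ks_score(
    ranked: RankedProfile, signature: GeneSignature | Sequence[str]
) -> float:
    """Signed rank-based enrichment score of the signature in a profile.

    Negative scores indicate the signature genes concentrate at the
    down-regulated end of the ranking (the perturbation opposes the
    signature).  Requires 0 < s < N.
    """
    genes = list(signature.genes if isinstance(signature, GeneSignature) else signature)
    universe = {g: i + 1 for i, g in enumerate(ranked.genes)}
    missing = [g for g in genes if g not in universe]
    if missing:
        raise ValueError(f"signature genes not in ranked universe: {missing}")
    s = len(genes)
    if s == 0:
        raise ValueError("signature is empty")
    if s >= ranked.n:
        raise ValueError("signature must be a proper subset of the gene universe")
    positions = np.sort(np.array([universe[g] for g in genes]))
    return _score_from_positions(positions, ranked.n)


def null_scores(n: int, s: int, R: int, seed: int = 0) -> np.ndarray:
    """Scores of R random gene sets of size s in an N-gene ranking.

    The null depends only on (N, s): random sets occupy uniformly random
    position sets regardless of which profile's ranking is used, so one
    null sample serves an entire screen.
    """
    if not 0 < s < n:
        raise ValueError("need 0 < s < n")
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    # R x s sorted positions drawn without replacement from 1..n
    positions = np.sort(np.argsort(rng.random((R, n)), axis=1)[:, :s], axis=1) + 1
    j = np.arange(1, s + 1)
    a = (j / s - positions / n).max(axis=1)
    b = (positions / n - (j - 1) / s).max(axis=1)
    return np.where(a >= b - 1e-12, a, -b)


def concordance_screen(
    reference: pd.DataFrame,
    signature: GeneSignature | Sequence[str],
    R: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    annotations: Mapping[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Score a signature against every perturbation profile in a reference.

    Parameters
    ----------
    reference
        Genes x perturbations matrix of differential-expression values.
    signature
        Up-regulated disease signature; genes absent from the reference
        universe are dropped (their count is recorded in
        ``result.attrs["n_dropped"]``), mirroring the intersection step a
        screen against a fixed platform requires.
    R
        Size of the random-gene-set null used for empirical p-values.
    annotations
        Optional perturbation -> target-annotation mapping copied into the
        output (empty string where unknown).

    Returns a DataFrame with one row per perturbation: ``score``,
    two-sided empirical ``p`` = (1 + #{|null| >= |score|}) / (R + 1),
    BH ``q``, and ``annotation``; ``attrs`` carries the signature
    intersection size.  Output is deterministic for a fixed seed.
    """
    genes = list(signature.genes if isinstance(signature, GeneSignature) else signature)
    if reference.index.has_duplicates:
        raise ValueError("reference gene universe contains duplicates")
    universe = reference.index
    present = [g for g in genes if g in universe]
    n_dropped = len(genes) - len(present)
    if not present:
        raise ValueError("no signature gene present in the reference universe")
    n = len(universe)
    s = len(present)
    if s >= n:
        raise ValueError("signature must be a proper subset of the gene universe")

    null = np.abs(null_scores(n, s, R, seed=seed))
    null_sorted = np.sort(null)

    scores = np.empty(reference.shape[1])
    # rank each column descending with gene-id ascending tie-break
    gene_ids = universe.to_numpy(dtype=object)
    id_order = np.argsort(gene_ids, kind="stable")
    sig_mask = np.asarray(universe.isin(present))
    for jcol, col in enumerate(reference.columns):
        vals = reference[col].to_numpy(dtype=float)
        # sort by (-value, gene id): stable sort on -value after id sort
        order = id_order[np.argsort(-vals[id_order], kind="stable")]
        positions = np.sort(np.nonzero(sig_mask[order])[0]) + 1
        scores[jcol] = _score_from_positions(positions, n)

    # #{|null| >= |score|} via sorted-null binary search
    n_ge = R - np.searchsorted(null_sorted, np.abs(scores) - 1e-12, side="left")
    p = (1 + n_ge) / (R + 1)
    q = bh_adjust(p)
    ann = pd.Series("", index=reference.columns, dtype=object)
    if annotations is not None:
        ann.update(pd.Series(annotations, dtype=object))
    out = pd.DataFrame(
        {
            "score": scores,
            "p": p,
            "q": q,
            "annotation": ann.to_numpy(),
        },
        index=pd.Index(reference.columns, name="perturbation"),
    )
    out.attrs["signature_size"] = s
    out.attrs["n_dropped"] = n_dropped
    out.attrs["alpha"] = alpha
    return out


def select_reversers(
    records: pd.DataFrame, alpha: float = 0.05, annotated_only: bool = False
) -> pd.DataFrame:
    """Filter a screen for significant signature-reversing perturbations.

    Keeps rows with score < 0 and q <= alpha, optionally restricted to
    annotated perturbagens, sorted most-negative-first (ties in score are
    ordered by perturbation identifier for determinism).  An empty result
    is allowed.
    """
    keep = (records["score"] < 0) & (records["q"] <= alpha)
    if annotated_only:
        keep &= records["annotation"].astype(str).str.len() > 0
    out = records.loc[keep].copy()
    # stable sort after an index sort -> score ties ordered by identifier
    return out.sort_index().sort_values("score", kind="stable")
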