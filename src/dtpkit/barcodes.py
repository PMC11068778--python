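"""Lineage-barcode whitelisting via an empirical Hamming-distance FDR.

A lentiviral barcode library tags each founding clone with a short static
DNA barcode (18 bp in the assay this package models).  Amplicon sequencing
of the barcode locus yields a count table in which true clone barcodes are
accompanied by sequencing-error satellites — low-count sequences one or two
substitutions away from an abundant parent.  The whitelisting procedure
ranks candidates by read count and, for each candidate list size ``k``,
estimates an empirical false discovery rate as the fraction of the top-k
candidates lying within a small Hamming distance of a higher-ranked
candidate.  The accepted whitelist is the largest ``k`` whose empirical FDR
stays at or below the threshold (0.05 by default).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BarcodeCountTable",
    "WhitelistResult",
    "ReadAssignment",
    "hamming",
    "count_barcodes",
    "estimate_whitelist",
    "assign_reads",
    "barcode_space_size",
]

_ALPHABET = "ACGT"


def hamming(a: str, b: str) -> int:
    """Number of mismatched positions between two equal-length sequences.

    Raises
    ------
    ValueError
        If the sequences differ in length.
    """
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class BarcodeCountTable:
    """Read counts per distinct barcode sequence.

    Attributes
    ----------
    counts : mapping barcode -> non-negative read count
    barcode_length : expected barcode length in bases
    n_discarded : reads discarded because their length differed from
        ``barcode_length`` (reported, never trimmed)
    """

    counts: dict[str, int]
    barcode_length: int
    n_discarded: int = 0

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("barcode count table must contain at least one entry")
        for bc, c in self.counts.items():
            if len(bc) != self.barcode_length:
                raise ValueError(
                    f"barcode {bc!r} has length {len(bc)}, expected {self.barcode_length}"
                )
            if c < 0:
                raise ValueError(f"negative count for barcode {bc!r}")

    @property
    def total_reads(self) -> int:
        return int(sum(self.counts.values()))

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"barcode": list(self.counts), "count": list(self.counts.values())}
        )
        return df.sort_values(
            ["count", "barcode"], ascending=[False, True], ignore_index=True
        )


@dataclass
class WhitelistResult:
    """Outcome of the empirical-FDR whitelisting procedure.

    ``fdr_curve[k]`` (1-based candidate size ``k``) is the fraction of the
    top-k ranked candidates flagged as likely sequencing errors; ``k_star``
    is the largest k with ``fdr_curve[k] <= threshold`` and ``whitelist``
    the corresponding top-k_star barcodes in rank order.
    """

    whitelist: list[str]
    k_star: int
    fdr_curve: pd.Series
    threshold: float
    ranked: list[str] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if self.fdr_curve.loc[self.k_star] > self.threshold + 1e-12:
            raise ValueError("k_star violates the FDR threshold")


def count_barcodes(reads: Iterable[str], barcode_length: int) -> BarcodeCountTable:
    """Tally distinct read sequences of the expected barcode length.

    Reads whose length differs from ``barcode_length`` are discarded and
    counted in ``n_discarded``.  Raises ``ValueError`` if no usable reads
    remain.
    """
    counts: Counter[str] = Counter()
    discarded = 0
    for r in reads:
        if len(r) == barcode_length:
            counts[r] += 1
        else:
            discarded += 1
    if not counts:
        raise ValueError(
            f"no reads of length {barcode_length} ({discarded} discarded)"
        )
    return BarcodeCountTable(dict(counts), barcode_length, discarded)


def _encode(barcodes: Sequence[str]) -> np.ndarray:
    """Barcodes as a (n, L) uint8 matrix of ASCII codes."""
    joined = "".join(barcodes).encode("ascii")
    return np.frombuffer(joined, dtype=np.uint8).reshape(len(barcodes), -1)


def _substitution_neighbors(barcode: str) -> Iterable[str]:
    """All sequences at Hamming distance exactly 1."""
    for i, base in enumerate(barcode):
        for alt in _ALPHABET:
            if alt != base:
                yield barcode[:i] + alt + barcode[i + 1 :]


def _neighbors_within(barcode: str, hd: int) -> Iterable[str]:
    """All sequences within Hamming distance 1..hd (substitutions only)."""
    L = len(barcode)
    for d in range(1, hd + 1):
        for positions in itertools.combinations(range(L), d):
            for alts in itertools.product(*(
                [a for a in _ALPHABET if a != barcode[i]] for i in positions
            )):
                chars = list(barcode)
                for i, a in zip(positions, alts):
                    chars[i] = a
                yield "".join(chars)


def _nearest_neighbor_rank(ranked: list[str], fp_hd: int) -> np.ndarray:
    """For each candidate, the best (smallest) rank of any other candidate
    within Hamming distance ``fp_hd``; table size if none.

    Uses neighbor enumeration for small fp_hd (fast for 18-mers), falling
    back to chunked pairwise distances for larger radii.
    """
    m = len(ranked)
    sentinel = m  # 0-based ranks; m means "no neighbor"
    best = np.full(m, sentinel, dtype=np.int64)
    L = len(ranked[0])
    n_neighbors = sum(
        3**d * len(list(itertools.combinations(range(L), d)))
        for d in range(1, fp_hd + 1)
    )
    if n_neighbors <= 5000:
        rank_of = {bc: i for i, bc in enumerate(ranked)}
        for i, bc in enumerate(ranked):
            hits = [
                rank_of[nb]
                for nb in _neighbors_within(bc, fp_hd)
                if nb in rank_of
            ]
            if hits:
                best[i] = min(hits)
        return best
    enc = _encode(ranked)
    chunk = max(1, 2**22 // max(m, 1))
    for start in range(0, m, chunk):
        block = enc[start : start + chunk]
        hd = (block[:, None, :] != enc[None, :, :]).sum(axis=2)
        for row in range(block.shape[0]):
            i = start + row
            hd[row, i] = L + 1  # exclude self
            within = np.nonzero(hd[row] <= fp_hd)[0]
            if within.size:
                best[i] = within[0]
    return best


def estimate_whitelist(
    counts: BarcodeCountTable | Mapping[str, int],
    threshold: float = 0.05,
    fp_hd: int = 1,
    compare: str = "higher",
) -> WhitelistResult:
    """Determine the clone-barcode whitelist by the empirical FDR cutoff.

    Candidates are ranked by read count (descending; ties broken by
    barcode string ascending).  For each candidate list size ``k`` the
    empirical FDR is the fraction of the top-k candidates within Hamming
    distance ``fp_hd`` of a comparison candidate; the whitelist is the
    top ``k_star`` where ``k_star`` is the largest k with FDR(k) <=
    ``threshold``.

    Parameters
    ----------
    counts
        A :class:`BarcodeCountTable` or plain barcode -> count mapping.
    threshold
        Empirical FDR bound, in (0, 1).  Default 0.05.
    fp_hd
        Hamming radius defining a likely sequencing-error satellite
        (default 1: single-substitution neighbors of a more abundant
        barcode are treated as false positives).
    compare
        ``"higher"`` (default): a candidate is flagged only when a
        higher-ranked candidate lies within ``fp_hd`` — sequencing errors
        derive from more abundant parents.  ``"all"``: flagged when any
        other top-k candidate lies within ``fp_hd``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if fp_hd < 1:
        raise ValueError("fp_hd must be >= 1")
    if compare not in ("higher", "all"):
        raise ValueError("compare must be 'higher' or 'all'")
    if not isinstance(counts, BarcodeCountTable):
        if not counts:
            raise ValueError("empty barcode count table")
        lengths = {len(b) for b in counts}
        if len(lengths) != 1:
            raise ValueError("barcodes have differing lengths")
        counts = BarcodeCountTable(dict(counts), lengths.pop())

    ranked = sorted(counts.counts, key=lambda b: (-counts.counts[b], b))
    m = len(ranked)
    best = _nearest_neighbor_rank(ranked, fp_hd)

    ks = np.arange(1, m + 1)
    if compare == "higher":
        # flagged iff some higher-ranked candidate is within fp_hd; such a
        # candidate is in every top-k that contains the flagged one, so the
        # flag is independent of k.
        is_fp = best < np.arange(m)
        n_fp = np.cumsum(is_fp)
    else:
        # flagged in top-k iff the nearest other candidate has rank < k
        # (0-based); count via the distribution of max(own rank, best rank).
        entry_k = np.maximum(np.arange(m), best) + 1  # k at which i is flagged
        n_fp = np.cumsum(np.bincount(entry_k, minlength=m + 2)[1 : m + 1])
    fdr = n_fp / ks
    passing = np.nonzero(fdr <= threshold)[0]
    # FDR(1) = 0 always, so there is at least one passing k.
    k_star = int(ks[passing[-1]])
    curve = pd.Series(fdr, index=pd.Index(ks, name="k"), name="fdr")
    return WhitelistResult(
        whitelist=ranked[:k_star],
        k_star=k_star,
        fdr_curve=curve,
        threshold=threshold,
        ranked=ranked,
    )


@dataclass
class ReadAssignment:
    """Per-read mapping to whitelist barcodes plus category tallies."""

    table: pd.DataFrame  # columns: read, assignment, status
    n_exact: int
    n_corrected: int
    n_unassigned: int
    n_ambiguous: int

    @property
    def total(self) -> int:
        return self.n_exact + self.n_corrected + self.n_unassigned + self.n_ambiguous


def assign_reads(
    reads: Sequence[str], whitelist: Sequence[str], max_hd: int = 1
) -> ReadAssignment:
    """Assign reads to whitelist barcodes, correcting up to ``max_hd`` errors.

    Each read is labeled ``exact`` (identical to a whitelist barcode),
    ``corrected`` (a unique whitelist barcode lies within ``max_hd``),
    ``ambiguous`` (two or more candidates, none exact) or ``unassigned``.
    An exact hit always wins: under a substitution-error model, zero
    mismatches is the maximum-likelihood origin even if another whitelist
    entry sits within the correction radius.
    """
    if not whitelist:
        raise ValueError("whitelist is empty")
    wl_set = set(whitelist)
    use_index = max_hd == 1 and len(whitelist) * len(whitelist[0]) * 3 < 5_000_000
    neighbor_of: dict[str, list[str]] = {}
    if use_index:
        for bc in whitelist:
            for nb in _substitution_neighbors(bc):
                neighbor_of.setdefault(nb, []).append(bc)

    rows = []
    n_exact = n_corr = n_unas = n_amb = 0
    for r in reads:
        if r in wl_set:
            rows.append((r, r, "exact"))
            n_exact += 1
            continue
        if use_index:
            cands = neighbor_of.get(r, []) if len(r) == len(whitelist[0]) else []
        else:
            cands = [
                bc
                for bc in whitelist
                if len(bc) == len(r) and hamming(r, bc) <= max_hd
            ]
        if len(cands) == 1:
            rows.append((r, cands[0], "corrected"))
            n_corr += 1
        elif len(cands) == 0:
            rows.append((r, None, "unassigned"))
            n_unas += 1
        else:
            rows.append((r, None, "ambiguous"))
            n_amb += 1
    table = pd.DataFrame(rows, columns=["read", "assignment", "status"])
    return ReadAssignment(table, n_exact, n_corr, n_unas, n_amb)


def barcode_space_size(length: int, alphabet_size: int = 4) -> int:
    """Exact number of distinct barcodes of the given length.

    For the 18-base static barcode this is 4**18 = 68,719,476,736,
    i.e. roughly 6.8e10 possible sequences.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    return alphabet_size**length
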