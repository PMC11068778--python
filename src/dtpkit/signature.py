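"""Gene-signature construction and scoring in labeled expression data.

The residual-disease (RD) signature workflow: label every cell by class
(e.g. "RD" vs "nonRD"), test each gene with an unpaired two-sample t-test,
BH-adjust, and define the signature as the genes significantly up-regulated
in *every* contributing dataset (intersection).  Set-level significance
uses the mean of the constituent genes' t statistics as the set statistic,
with a class-label permutation null.  Per-cell signature scores are the
mean normalized expression over signature genes.

Expression is normalized per cell to counts-per-10k then log(1+x) by
default (``normalize="cp10k_log1p"``); pass ``normalize="raw"`` to test or
score the matrix as given.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSignature",
    "SetTestResult",
    "normalize_matrix",
    "per_gene_tstat",
    "bh_adjust",
    "build_intersection_signature",
    "permutation_set_test",
    "score_cells",
]


@dataclass
class GeneSignature:
    """An ordered set of up-regulated genes with provenance."""

    genes: list[str]
    direction: str = "up"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature gene identifiers must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def is_empty(self) -> bool:
        return not self.genes


@dataclass
class SetTestResult:
    """Permutation test of a gene set's mean t statistic."""

    t_obs: float
    n_permutations: int
    p: float
    method: str = "sample"

    def __post_init__(self) -> None:
        lo = 1.0 / (self.n_permutations + 1)
        if not lo - 1e-12 <= self.p <= 1 + 1e-12:
            raise ValueError("permutation p outside its attainable range")


def _dense(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    return np.asarray(X, dtype=float)


def normalize_matrix(x: np.ndarray, mode: str = "cp10k_log1p") -> np.ndarray:
    """Per-cell normalization of a cells x genes matrix.

    ``cp10k_log1p`` scales each cell to 10,000 total counts then applies
    log(1+x); ``raw`` returns the matrix unchanged.
    """
    if mode == "raw":
        return np.asarray(x, dtype=float)
    if mode != "cp10k_log1p":
        raise ValueError(f"unknown normalization mode {mode!r}")
    x = np.asarray(x, dtype=float)
    totals = x.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("cells with zero total expression cannot be normalized")
    return np.log1p(x / totals * 1e4)


def _class_split(
    adata: ad.AnnData, label_col: str, target: str
) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(adata.obs[label_col])
    mask = labels == target
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each class needs at least two cells")
    return mask, ~mask


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise pooled-variance two-sample t (a vs b) and two-sided p.

    Genes with zero pooled variance get t = 0, p = 1 when the means agree
    (and +/-inf handled to t=0 never occurs there since scipy returns inf;
    we only patch the 0/0 case).
    """
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant genes trip scipy's precision-loss warning; the 0/0 and
        # x/0 cases are patched explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        mean_diff = a.mean(axis=0) - b.mean(axis=0)
        zero_diff = degenerate & (np.abs(mean_diff) < 1e-12)
        t[zero_diff] = 0.0
        p[zero_diff] = 1.0
        # zero variance but different means: infinitely significant
        inf_sig = degenerate & ~zero_diff
        t[inf_sig] = np.sign(mean_diff[inf_sig]) * np.inf
        p[inf_sig] = 0.0
    return t, p


def per_gene_tstat(
    adata: ad.AnnData,
    target: str,
    label_col: str = "label",
    normalize: str = "cp10k_log1p",
    welch: bool = False,
) -> pd.DataFrame:
    """Unpaired two-sample t-test per gene, target class vs the rest.

    Returns a DataFrame indexed by gene with columns ``t`` (positive when
    the target class mean is higher), ``p`` (two-sided), ``q`` (BH) and
    ``direction`` ("up"/"down").  The classical pooled-variance test is the
    default; ``welch=True`` drops the equal-variance assumption.
    """
    mask_a, mask_b = _class_split(adata, label_col, target)
    x = normalize_matrix(_dense(adata), normalize)
    a, b = x[mask_a], x[mask_b]
    if welch:
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
        t, p = np.asarray(t, float), np.asarray(p, float)
        bad = ~np.isfinite(t)
        t[bad], p[bad] = 0.0, 1.0
    else:
        t, p = _pooled_t(a, b)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "t": t,
            "p": p,
            "q": q,
            "direction": np.where(t > 0, "up", "down"),
        },
        index=adata.var_names.copy(),
    )


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_intersection_signature(
    stat_tables: Mapping[str, pd.DataFrame], alpha: float = 0.05
) -> GeneSignature:
    """Signature = genes significantly up-regulated in every table.

    Each table must carry ``q`` and ``direction`` columns (the output of
    :func:`per_gene_tstat`).  A gene enters the signature iff q < alpha and
    direction == "up" in all tables.  An empty intersection returns an
    empty signature with a warning, not an error, so callers can inspect
    the provenance.
    """
    if len(stat_tables) < 2:
        raise ValueError("need at least two stat tables to intersect")
    up_sets = []
    for name, table in stat_tables.items():
        up = set(table.index[(table["q"] < alpha) & (table["direction"] == "up")])
        up_sets.append(up)
    genes = sorted(set.intersection(*up_sets))
    if not genes:
        warnings.warn(
            "intersection of significantly up-regulated genes is empty",
            stacklevel=2,
        )
    return GeneSignature(genes=genes, direction="up", provenance=list(stat_tables))


def _set_stat(x: np.ndarray, mask_a: np.ndarray) -> float:
    """Mean of per-gene pooled t statistics over the (pre-subset) matrix."""
    t, _ = _pooled_t(x[mask_a], x[~mask_a])
    if not np.isfinite(t).all():
        # +/-inf from zero-variance genes: cap so the mean stays finite
        t = np.where(np.isfinite(t), t, np.sign(t) * 1e12)
    return float(np.mean(t))


def permutation_set_test(
    adata: ad.AnnData,
    signature: GeneSignature | Sequence[str],
    target: str,
    B: int = 1000,
    seed: int = 0,
    label_col: str = "label",
    normalize: str = "cp10k_log1p",
    method: str = "sample",
) -> SetTestResult:
    """Class-label permutation test of the signature's mean t statistic.

    The observed set statistic T_obs is the mean of the signature genes' t
    statistics (target class vs rest).  Under ``method="sample"`` the class
    labels are shuffled ``B`` times (seeded) and the two-sided empirical p
    uses the add-one estimator p = (1 + #{|T_perm| >= |T_obs|}) / (B + 1),
    so p is never exactly 0.  ``method="exact"`` enumerates every distinct
    assignment of the target-class size to cell positions (excluding the
    observed one), which at small n reproduces the exhaustive permutation
    distribution exactly.
    """
    genes = list(signature.genes if isinstance(signature, GeneSignature) else signature)
    if not genes:
        raise ValueError("signature is empty")
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise ValueError(f"signature genes absent from matrix: {missing}")
    if B < 1:
        raise ValueError("B must be >= 1")
    mask_a, _ = _class_split(adata, label_col, target)
    x_full = normalize_matrix(_dense(adata), normalize)
    col_idx = [adata.var_names.get_loc(g) for g in genes]
    x = x_full[:, col_idx]
    t_obs = _set_stat(x, mask_a)

    n = x.shape[0]
    n_a = int(mask_a.sum())
    if method == "exact":
        perms = []
        observed = frozenset(np.nonzero(mask_a)[0].tolist())
        for combo in itertools.combinations(range(n), n_a):
            if frozenset(combo) != observed:
                perms.append(np.array(combo))
        B = len(perms)
        count = 0
        for combo in perms:
            m = np.zeros(n, dtype=bool)
            m[combo] = True
            if abs(_set_stat(x, m)) >= abs(t_obs) - 1e-12:
                count += 1
        p = (1 + count) / (B + 1)
        return SetTestResult(t_obs=t_obs, n_permutations=B, p=p, method="exact")
    if method != "sample":
        raise ValueError("method must be 'sample' or 'exact'")
    rng = np.random.default_rng(seed)
    count = 0
    idx = np.arange(n)
    for _ in range(B):
        perm = rng.permutation(idx)
        m = np.zeros(n, dtype=bool)
        m[perm[:n_a]] = True
        if abs(_set_stat(x, m)) >= abs(t_obs) - 1e-12:
            count += 1
    p = (1 + count) / (B + 1)
    return SetTestResult(t_obs=t_obs, n_permutations=B, p=p, method="sample")


def score_cells(
    adata: ad.AnnData,
    signature: GeneSignature | Sequence[str],
    normalize: str = "cp10k_log1p",
    allow_missing: bool = False,
) -> pd.Series:
    """Per-cell signature score: mean normalized expression over the set.

    Genes absent from the matrix raise an error unless ``allow_missing``
    is set, in which case they are dropped (and at least one gene must
    remain).
    """
    genes = list(signature.genes if isinstance(signature, GeneSignature) else signature)
    if not genes:
        raise ValueError("signature is empty")
    present = [g for g in genes if g in adata.var_names]
    missing = sorted(set(genes) - set(present))
    if missing and not allow_missing:
        raise ValueError(f"signature genes absent from matrix: {missing}")
    if not present:
        raise ValueError("no signature gene present in the matrix")
    x = normalize_matrix(_dense(adata), normalize)
    col_idx = [adata.var_names.get_loc(g) for g in present]
    scores = x[:, col_idx].mean(axis=1)
    return pd.Series(scores, index=adata.obs_names.copy(), name="signature_score")
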