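"""Synthetic inputs with the statistical structure the analyses assume.

Each generator emulates one data modality of a lineage-traced
drug-tolerant-persister study, with full ground truth returned alongside
the data so downstream estimators can be validated without any external
download:

* clone barcode libraries (18-bp static barcodes, well separated in
  Hamming space, as delivered at low MOI ~0.1) and amplicon reads with
  per-base substitution errors;
* labeled cell x gene expression matrices with a planted set of
  up-regulated signature genes in one class;
* drug-perturbation reference matrices with planted signature-reversing
  (and signature-mimicking) perturbagens;
* two-channel fluorescence images of disk-like nuclei with known
  per-nucleus integrated densities.

All generators are deterministic given their integer seed.  FASTQ quality
is fixed at a constant high score; quality is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .barcodes import hamming

__all__ = [
    "SimBarcodeTruth",
    "SimExpressionTruth",
    "SimReferenceTruth",
    "SimImageTruth",
    "gen_true_barcodes",
    "gen_reads",
    "gen_labeled_expression",
    "gen_drug_reference",
    "gen_nuclei_image",
]

_ALPHABET = "ACGT"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# rejection-sampling cap: deterministic failure beats silent degradation
_MAX_ATTEMPTS_PER_BARCODE = 10_000


@dataclass
class SimBarcodeTruth:
    """Ground truth for a simulated clone-barcode library."""

    barcodes: list[str]
    abundance: np.ndarray
    error_rate: float = 0.0
    seed: int = 0
    min_hd: int = 0  # asserted minimum pairwise Hamming distance (0 = unchecked)

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("barcode list is empty")
        L = len(self.barcodes[0])
        if any(len(b) != L for b in self.barcodes):
            raise ValueError("barcodes must all have the same length")
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.shape != (len(self.barcodes),):
            raise ValueError("abundance must match the number of barcodes")
        if (self.abundance < 0).any():
            raise ValueError("abundance must be non-negative")
        if abs(self.abundance.sum() - 1.0) > 1e-9:
            raise ValueError("abundance must sum to 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.min_hd > 0:
            for i, a in enumerate(self.barcodes):
                for b in self.barcodes[i + 1 :]:
                    if hamming(a, b) < self.min_hd:
                        raise ValueError(
                            f"barcodes {a!r} and {b!r} closer than min_hd={self.min_hd}"
                        )

    @property
    def length(self) -> int:
        return len(self.barcodes[0])


def gen_true_barcodes(n: int, length: int, min_hd: int, seed: int = 0) -> list[str]:
    """Draw ``n`` distinct barcodes with pairwise Hamming distance >= ``min_hd``.

    Rejection sampling with a cap of 10,000 attempts per requested barcode;
    an infeasible (n, length, min_hd) combination raises ``ValueError``
    rather than silently degrading the separation guarantee.
    """
    if min_hd < 1:
        raise ValueError("min_hd must be >= 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > 4**length:
        raise ValueError(f"cannot draw {n} distinct barcodes of length {length}")
    rng = np.random.default_rng(seed)
    accepted = np.empty((0, length), dtype=np.uint8)
    out: list[str] = []
    attempts_left = _MAX_ATTEMPTS_PER_BARCODE * n
    while len(out) < n:
        if attempts_left <= 0:
            raise ValueError(
                f"could not place {n} barcodes of length {length} with "
                f"min_hd={min_hd} within the attempt budget"
            )
        attempts_left -= 1
        cand = rng.integers(0, 4, size=length).astype(np.uint8)
        if accepted.size and int((accepted != cand).sum(axis=1).min()) < min_hd:
            continue
        accepted = np.vstack([accepted, cand])
        out.append("".join(_ALPHABET[c] for c in cand))
    return out


def gen_reads(truth: SimBarcodeTruth, n_reads: int, seed: int = 0) -> list[str]:
    """Simulate amplicon reads of the barcode locus.

    Each read's template is drawn from ``truth.abundance``; each base is
    then substituted independently with probability ``truth.error_rate``
    (uniform over the three alternative bases).  Returns plain sequence
    strings; see :func:`dtpkit.io.write_fastq` for FASTQ output.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    L = truth.length
    codes = np.frombuffer("".join(truth.barcodes).encode(), dtype=np.uint8)
    templates = np.searchsorted(_BASES, codes).reshape(len(truth.barcodes), L)
    # _BASES is sorted (A<C<G<T), so searchsorted maps base -> 0..3
    idx = rng.choice(len(truth.barcodes), size=n_reads, p=truth.abundance)
    reads = templates[idx].copy()
    if truth.error_rate > 0:
        mask = rng.random((n_reads, L)) < truth.error_rate
        shifts = rng.integers(1, 4, size=int(mask.sum()))
        reads[mask] = (reads[mask] + shifts) % 4
    ascii_codes = _BASES[reads]
    flat = ascii_codes.tobytes()
    return [flat[i * L : (i + 1) * L].decode("ascii") for i in range(n_reads)]


@dataclass
class SimExpressionTruth:
    """Ground truth for a labeled expression matrix with planted signal.

    ``signature_genes`` are shifted upward by ``effect_size`` (log scale)
    in ``target_class`` cells only; every other gene is exchangeable
    between classes.  Noise is log-normal: expression = exp(N(mu, sigma)),
    keeping values positive on a log1p-like scale where a two-sample t-test
    is well behaved.
    """

    n_cells_per_class: dict[str, int]
    genes: list[str]
    signature_genes: list[str] = field(default_factory=list)
    target_class: str = ""
    effect_size: float = 0.0
    log_mean: float = 1.0
    log_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_cells_per_class) < 2:
            raise ValueError("need at least two cell classes")
        if any(n < 2 for n in self.n_cells_per_class.values()):
            raise ValueError("need at least two cells per class")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        missing = set(self.signature_genes) - set(self.genes)
        if missing:
            raise ValueError(f"signature genes not in gene list: {sorted(missing)}")
        if self.signature_genes and self.effect_size > 0 and not self.target_class:
            raise ValueError("target_class required when planting an effect")
        if self.target_class and self.target_class not in self.n_cells_per_class:
            raise ValueError(f"unknown target class {self.target_class!r}")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")


def gen_labeled_expression(truth: SimExpressionTruth) -> ad.AnnData:
    """Generate a cells x genes AnnData with per-cell class labels.

    ``adata.obs["label"]`` carries the class; ``adata.var["is_signature"]``
    flags planted genes.  Values are positive (log-normal noise), suitable
    for the CP10k + log1p normalization used downstream.
    """
    rng = np.random.default_rng(truth.seed)
    classes = list(truth.n_cells_per_class)
    n_total = sum(truth.n_cells_per_class.values())
    n_genes = len(truth.genes)
    log_x = rng.normal(truth.log_mean, truth.log_sigma, size=(n_total, n_genes))
    labels = np.repeat(classes, [truth.n_cells_per_class[c] for c in classes])
    if truth.signature_genes and truth.effect_size > 0:
        gene_idx = [truth.genes.index(g) for g in truth.signature_genes]
        row_mask = labels == truth.target_class
        log_x[np.ix_(row_mask, gene_idx)] += truth.effect_size
    adata = ad.AnnData(
        X=np.exp(log_x),
        obs=pd.DataFrame(
            {"label": pd.Categorical(labels)},
            index=[f"cell_{i}" for i in range(n_total)],
        ),
        var=pd.DataFrame(
            {"is_signature": [g in set(truth.signature_genes) for g in truth.genes]},
            index=truth.genes,
        ),
    )
    return adata


@dataclass
class SimReferenceTruth:
    """Ground truth for a drug-perturbation reference matrix."""

    n_perturbations: int
    planted_reversers: list[str] = field(default_factory=list)
    planted_mimics: list[str] = field(default_factory=list)
    n_genes: int = 978
    effect: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perturbations < 1:
            raise ValueError("need at least one perturbation")
        if set(self.planted_reversers) & set(self.planted_mimics):
            raise ValueError("planted reverser and mimic sets must be disjoint")
        ids = set(self.perturbation_ids)
        unknown = (set(self.planted_reversers) | set(self.planted_mimics)) - ids
        if unknown:
            raise ValueError(f"planted perturbations not in id range: {sorted(unknown)}")

    @property
    def perturbation_ids(self) -> list[str]:
        return [f"pert_{i:04d}" for i in range(self.n_perturbations)]


def gen_drug_reference(
    truth: SimReferenceTruth, signature_genes: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a gene x perturbation differential-expression reference.

    Emulates an L1000-style level-4 matrix: one z-score-like profile per
    perturbagen over a fixed gene universe containing the signature genes.
    Planted reversers push signature genes strongly negative (down-ranked),
    planted mimics strongly positive; all other entries are independent
    standard normal noise.

    Returns ``(reference, truth_table)`` where ``truth_table`` has columns
    ``perturbation``, ``role`` (reverser/mimic/noise) and ``annotation``
    (a mock target string for planted perturbagens, empty otherwise).
    """
    signature_genes = list(signature_genes)
    if not signature_genes:
        raise ValueError("signature is empty")
    rng = np.random.default_rng(truth.seed)
    n_sig = len(signature_genes)
    other = [f"gene_{i:04d}" for i in range(truth.n_genes)]
    universe = signature_genes + [g for g in other if g not in set(signature_genes)]
    perts = truth.perturbation_ids
    values = rng.normal(0.0, 1.0, size=(len(universe), len(perts)))
    roles = []
    annotations = []
    for j, p in enumerate(perts):
        if p in truth.planted_reversers:
            values[:n_sig, j] -= truth.effect
            roles.append("reverser")
            annotations.append(f"target_of_{p}")
        elif p in truth.planted_mimics:
            values[:n_sig, j] += truth.effect
            roles.append("mimic")
            annotations.append(f"target_of_{p}")
        else:
            roles.append("noise")
            annotations.append("")
    reference = pd.DataFrame(values, index=pd.Index(universe, name="gene"), columns=perts)
    truth_table = pd.DataFrame(
        {"perturbation": perts, "role": roles, "annotation": annotations}
    )
    return reference, truth_table


@dataclass
class SimImageTruth:
    """Ground truth for a two-channel nuclei image.

    ``intensities`` are per-nucleus protein-channel pixel values (flat
    across the disk); the nuclear-stain channel marks every disk at
    ``stain_level``.  Nuclei must lie fully inside the image and respect a
    pairwise margin so segmentation cannot merge them.
    """

    centers: list[tuple[int, int]]
    radii: list[float]
    intensities: list[float]
    shape: tuple[int, int] = (256, 256)
    background: float = 10.0
    stain_level: float = 200.0
    margin: float = 2.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.centers)
        if len(self.radii) != k or len(self.intensities) != k:
            raise ValueError("centers, radii and intensities must have equal length")
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")
        if any(v < self.background for v in self.intensities):
            raise ValueError("nucleus intensities must be >= background")
        h, w = self.shape
        for (r0, c0), rad in zip(self.centers, self.radii):
            if r0 - rad < 0 or r0 + rad >= h or c0 - rad < 0 or c0 + rad >= w:
                raise ValueError(f"nucleus at {(r0, c0)} extends outside the image")
        for i in range(k):
            for j in range(i + 1, k):
                d = np.hypot(
                    self.centers[i][0] - self.centers[j][0],
                    self.centers[i][1] - self.centers[j][1],
                )
                if d < self.radii[i] + self.radii[j] + self.margin:
                    raise ValueError(f"nuclei {i} and {j} overlap (margin {self.margin})")


def gen_nuclei_image(
    truth: SimImageTruth,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render the two channels and the per-nucleus truth table.

    Returns ``(nuclear_channel, protein_channel, truth_table)``; channels
    are float64 grids, the table lists each nucleus's pixel area and
    noiseless integrated density (intensity x area, the sum of protein
    pixel values over the disk).
    """
    h, w = truth.shape
    nuclear = np.full((h, w), truth.background, dtype=float)
    protein = np.full((h, w), truth.background, dtype=float)
    rows = []
    rr, cc = np.mgrid[0:h, 0:w]
    for k, ((r0, c0), rad, inten) in enumerate(
        zip(truth.centers, truth.radii, truth.intensities), start=1
    ):
        disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        nuclear[disk] = truth.stain_level
        protein[disk] = inten
        area = int(disk.sum())
        rows.append((k, r0, c0, area, inten, inten * area))
    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.seed)
        nuclear = nuclear + rng.normal(0, truth.noise_sigma, size=(h, w))
        protein = protein + rng.normal(0, truth.noise_sigma, size=(h, w))
        np.clip(nuclear, 0, None, out=nuclear)
        np.clip(protein, 0, None, out=protein)
    table = pd.DataFrame(
        rows,
        columns=["nucleus", "row", "col", "area", "intensity", "integrated_density"],
    )
    return nuclear, protein, table
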