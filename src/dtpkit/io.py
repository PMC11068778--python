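"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTQ via Biopython, expression matrices as MTX triplets (scipy sparse +
gene/cell TSVs) or dense TSV via anndata/pandas, gene sets as GMT,
count/abundance tables as two-column TSV, images as 16-bit grayscale TIFF
(one file per channel) via tifffile.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as spio
from scipy import sparse

from .signature import GeneSignature

__all__ = [
    "write_fastq",
    "read_fastq",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_expression",
    "read_expression",
    "read_gmt",
    "write_gmt",
    "write_image",
    "read_image",
]

_FASTQ_QUALITY = 40  # constant high score; quality is not modeled


def _sibling(prefix: Path, ext: str) -> Path:
    return prefix.parent / (prefix.name + ext)


def write_fastq(reads: Sequence[str], path: str | Path, prefix: str = "read") -> None:
    records = [
        SeqRecord(
            Seq(r),
            id=f"{prefix}_{i}",
            description="",
            letter_annotations={"phred_quality": [_FASTQ_QUALITY] * len(r)},
        )
        for i, r in enumerate(reads)
    ]
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def write_counts_tsv(counts: Mapping[str, int], path: str | Path) -> None:
    pd.Series(counts, name="count").rename_axis("barcode").to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(int)))


def write_expression(adata: ad.AnnData, prefix: str | Path, dense: bool = False) -> None:
    """Write an expression matrix as dense TSV or an MTX triplet.

    Dense: ``<prefix>.tsv`` (cells x genes) plus ``<prefix>.labels.tsv``.
    Sparse: ``<prefix>.mtx`` (genes x cells, MatrixMarket) with
    ``<prefix>.genes.tsv``, ``<prefix>.cells.tsv`` and labels.
    """
    prefix = Path(prefix)
    labels = adata.obs.reset_index().rename(columns={"index": "cell"})
    labels.to_csv(_sibling(prefix, ".labels.tsv"), sep="\t", index=False)
    X = adata.X.toarray() if hasattr(adata.X, "toarray") else np.asarray(adata.X)
    if dense:
        pd.DataFrame(X, index=adata.obs_names, columns=adata.var_names).rename_axis(
            "cell"
        ).to_csv(_sibling(prefix, ".tsv"), sep="\t")
    else:
        spio.mmwrite(str(_sibling(prefix, ".mtx")), sparse.csr_matrix(X.T))
        pd.Series(adata.var_names).to_csv(
            _sibling(prefix, ".genes.tsv"), sep="\t", index=False, header=False
        )
        pd.Series(adata.obs_names).to_csv(
            _sibling(prefix, ".cells.tsv"), sep="\t", index=False, header=False
        )


def read_expression(prefix: str | Path, label_col: str = "label") -> ad.AnnData:
    """Read an expression matrix written by :func:`write_expression`."""
    prefix = Path(prefix)
    if _sibling(prefix, ".mtx").exists():
        X = spio.mmread(str(_sibling(prefix, ".mtx"))).toarray().T
        genes = pd.read_csv(
            _sibling(prefix, ".genes.tsv"), sep="\t", header=None
        )[0].tolist()
        cells = pd.read_csv(
            _sibling(prefix, ".cells.tsv"), sep="\t", header=None
        )[0].tolist()
        df = pd.DataFrame(X, index=cells, columns=genes)
    else:
        df = pd.read_csv(_sibling(prefix, ".tsv"), sep="\t", index_col=0)
    obs = pd.DataFrame(index=df.index)
    labels_path = _sibling(prefix, ".labels.tsv")
    if labels_path.exists():
        labels = pd.read_csv(labels_path, sep="\t", index_col=0)
        obs = labels.reindex(df.index)
    adata = ad.AnnData(X=df.to_numpy(dtype=float), obs=obs)
    adata.var_names = df.columns
    if label_col in adata.obs:
        adata.obs[label_col] = pd.Categorical(adata.obs[label_col])
    return adata


def read_gmt(path: str | Path) -> dict[str, GeneSignature]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, GeneSignature] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        sets[name] = GeneSignature(
            genes=genes, provenance=[desc] if desc else []
        )
    return sets


def write_gmt(
    signatures: Mapping[str, GeneSignature | Iterable[str]], path: str | Path
) -> None:
    lines = []
    for name, sig in signatures.items():
        genes = list(sig.genes if isinstance(sig, GeneSignature) else sig)
        desc = (
            "&".join(sig.provenance)
            if isinstance(sig, GeneSignature) and sig.provenance
            else "na"
        )
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write one channel as 16-bit grayscale TIFF (values clipped)."""
    arr = np.clip(np.asarray(image), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(str(path), np.round(arr).astype(np.uint16))


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)
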