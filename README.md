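# dtpkit

Analysis toolkit for lineage-traced studies of drug-tolerant persister
(DTP) cells and residual disease (RD) in targeted cancer therapy.

When an oncogene-driven tumor cell line is treated with a targeted
inhibitor, a small subpopulation survives in a drug-tolerant state.
Characterizing where these persisters come from and what transcriptional
program they run requires several bespoke computational steps that sit
between standard pipelines: calling true clone barcodes out of noisy
amplicon sequencing, quantifying clonal diversity over a treatment
trajectory, defining an up-regulated gene signature shared across models
and patients, screening a drug-perturbation reference for compounds that
reverse that signature, and quantifying nuclear protein levels in
microscopy images. `dtpkit` implements each of these as a tested,
reusable library with a synthetic-data module so every stage can be
validated against known ground truth.

## The methods

**Barcode whitelisting with an empirical Hamming-distance FDR.**
Clone barcodes (18-bp random DNA tags delivered at MOI ≈ 0.1) are
sequenced as amplicons; sequencing errors surround each true barcode with
low-count satellites. Candidates are ranked by read count, and for each
candidate-list size *k* the empirical FDR is the fraction of the top-*k*
sequences lying within Hamming distance 1 of a higher-ranked candidate.
The whitelist is the largest *k* with FDR(*k*) ≤ 0.05.

**Lineage diversity.** For barcode-group relative abundances *pᵢ*, the
diversity index is `1 − Σᵢ pᵢ²`, maximal at `1 − 1/n` for *n* equally
abundant groups; the scaled index divides by that maximum. Enrichment
shifts between timepoints are tested per group with a Fisher exact test
and Benjamini–Hochberg correction.

**Signature construction and scoring.** Each gene is tested RD vs non-RD
with an unpaired (pooled-variance) t-test; BH-adjusted; the signature is
the intersection of significantly up-regulated genes (q < 0.05) across
datasets. Set-level significance uses the mean of the constituent genes'
t statistics against a class-label permutation null; per-cell scores are
mean normalized (CP10k, log1p) expression over signature genes.

**Drug-concordance screening.** Each perturbation profile in a gene ×
perturbation reference (L1000-level-4-like) is ranked most-up-first and
scored with a signed rank-based statistic similar to the Kolmogorov–
Smirnov statistic: with signature positions *p₁ < … < p_s* among *N*
genes, `a = maxⱼ(j/s − pⱼ/N)`, `b = maxⱼ(pⱼ/N − (j−1)/s)`, score `= a`
if `a ≥ b` else `−b`. Negative scores mean the drug down-ranks
(reverses) the signature. Empirical p-values come from random gene sets
of equal size; reversal candidates are significantly negative scorers
after BH at α = 0.05.

**Nuclear intensity quantification.** Nuclei are segmented on the
nuclear-stain channel (Otsu threshold, hole filling, 8-connected
labeling, minimum area 50 px); the integrated density of a nucleus is the
sum of protein-channel intensities over its pixels, reported relative to
the mean integrated density of a control image.

## Worked example

```sh
python examples/barcode_whitelisting.py
```

simulates 100 true barcodes, 100,000 reads at a 0.5% per-base error rate,
and whitelists:

```
distinct sequences observed : 3756
whitelist size k*           : 105
empirical FDR at k*         : 0.0476
false barcodes admitted     : 5 (satellites below the 5% bound)
true barcodes missed        : 0
```

Of 3,756 distinct observed sequences, the empirical-FDR cutoff keeps 105:
all 100 true clones plus 5 error satellites — an actual false-discovery
proportion of 4.8%, inside the 5% bound the threshold promises. The other
capabilities have matching narrative scripts in `examples/`
(`lineage_diversity.py`, `signature_workflow.py`,
`drug_reversal_screen.py`, `nuclear_intensity.py`), and each pipeline
stage is also exposed through the `dtpkit` command line
(`dtpkit simulate|whitelist|diversity|signature|concordance|imagequant`).

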