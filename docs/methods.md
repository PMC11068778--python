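# Methods

This note documents the models, parameter choices and known limitations
behind each `dtpkit` module, in the order a study would use them.

## Synthetic data (`dtpkit.simulate`)

The generators produce inputs with the statistical structure the
estimators assume, plus full ground truth, so every downstream stage is
testable without external data.

**Barcode libraries and reads.** True barcodes are uniform random DNA
strings accepted by rejection sampling until all pairwise Hamming
distances reach `min_hd` (default 3 in the study-scale settings, so that
single-substitution satellites of one clone can never collide with
another clone). The attempt budget is 10,000·n; exhausting it raises an
error rather than silently relaxing the separation guarantee. Reads draw
a template from the clone abundance vector and substitute each base
independently with probability `error_rate`, uniformly over the three
alternative bases. Defaults mirror the assay being emulated: 18-bp
barcodes, 0.005 per-base substitution rate, log-normal clone abundances
(σ = 1) reflecting the unequal clone sizes that arise after expansion
from a bottleneck. Indels, PCR amplification bias, UMIs and
quality-dependent errors are not modeled; FASTQ quality is a constant
high score. The substitution-only error model is a stand-in — the
sequencing platform's true error process is more structured — so
whitelisting results on synthetic reads demonstrate correctness of the
procedure, not platform-level error rates.

**Labeled expression.** Expression is exp(N(μ, σ)) per cell × gene
(log-normal, default μ = 1, σ = 1 on the log scale — the simplest noise
model that keeps values positive and leaves a two-sample t-test well
behaved after log transformation). Signature genes in the target class
are shifted by `effect_size` on the log scale; all other genes are
exchangeable between classes. Real single-cell data additionally carry
zero inflation, library-size variation and gene–gene correlation; tests
passing here show the testing/intersection machinery is correct, not that
its power estimates transfer to real droplet data.

**Drug reference.** A gene × perturbation matrix of independent standard
normal values, emulating z-scored level-4 perturbation profiles over a
978-gene universe. Planted reversers subtract (and mimics add) an effect
of 3 from the signature genes' entries — large enough that a planted
perturbagen should dominate a screen, which is exactly what the recovery
tests assert.

**Nuclei images.** Disk-shaped nuclei with flat per-nucleus protein
intensity on a constant background, optional Gaussian pixel noise, with
bounds and pairwise-margin checks enforced at construction (the
segmentation chain deliberately has no touching-nuclei splitting). The
truth table records intensity × area, the noiseless integrated density.

All generators consume one explicit integer seed and are bit-reproducible
given it.

## Barcode whitelisting (`dtpkit.barcodes`)

Candidates are ranked by read count descending, ties broken
lexicographically for determinism. A candidate is flagged as a likely
false positive when it lies within Hamming distance `fp_hd` (default 1)
of a **higher-ranked** candidate: sequencing errors derive from more
abundant parents, and an all-pairs rule would also flag the parent
(double-counting). The all-pairs variant remains available via
`compare="all"` for comparison. FDR(k) is the flagged fraction of the
top-k; the whitelist is the largest k with FDR(k) ≤ threshold (default
0.05). Scanning all k and taking the largest passing k maximizes
recovered clones while honoring the bound; because FDR(k) returns below
the threshold whenever fewer than threshold·k candidates are flagged,
the procedure intentionally admits a small tail of flagged satellites —
its guarantee is a bounded false-discovery proportion, not exact
recovery. With the default `fp_hd = 1`, flagging uses exact
substitution-neighbor lookup (54 neighbors per 18-mer), so whitelisting
tens of thousands of candidates takes about a second; larger radii fall
back to chunked pairwise distance computation.

Read assignment corrects reads to a unique whitelist barcode within
`max_hd` (default 1). A read identical to a whitelist entry is always
labeled `exact`, even if a second entry lies within the correction
radius: zero mismatches is the maximum-likelihood origin under the
substitution model. Non-exact reads with two or more candidates are
`ambiguous`; with none, `unassigned`. The four categories partition the
input. Reads of the wrong length are discarded and counted, never
trimmed.

## Lineage diversity (`dtpkit.diversity`)

The index `1 − Σ pᵢ²` is the probability that two cells drawn at random
belong to different lineages; the scaled index divides by the maximum
`1 − 1/n` so trajectories with different group counts are comparable (it
is undefined for n = 1, which is an error rather than a silent 0/0).

The enrichment-shift test uses a per-group 2×2 Fisher exact test (group
vs rest, timepoint 0 vs 1) with BH correction; an exact test was chosen
because group counts can be small. Groups absent at one timepoint enter
with count 0 over the union universe — the disappearance of a lineage is
itself a shift the test must be able to see. The summary flag is True
iff any group reaches q ≤ α. Note the test detects *relative* frequency
shifts: a strong expansion of one clone dilutes all others, which can
legitimately flag additional groups at high sequencing depth.

## Signature scoring (`dtpkit.signature`)

"Unpaired t-test" is implemented as the classical pooled-variance
two-sample t (Welch available via `welch=True`). Genes with zero pooled
variance get t = 0, p = 1 when the class means agree, and infinite
significance when they differ (capped at ±1e12 inside set statistics so
means stay finite). Expression is normalized per cell to 10,000 counts
then log(1 + x) before testing and scoring; the raw mode skips this. The
CP10k + log choice is a standard single-cell convention adopted as a
design decision, not an inference about any particular upstream
pipeline.

BH adjustment delegates to statsmodels' step-up implementation; the
signature is the intersection of genes with q < α and direction up in
every contributing table, sorted lexicographically, with the table names
kept as provenance. An empty intersection warns but returns an empty
signature so callers can inspect why.

The permutation set test uses the mean of signature genes' t statistics
as the set statistic and permutes class labels. The sampled mode draws B
seeded shuffles and reports the add-one two-sided estimator
p = (1 + #{|T_perm| ≥ |T_obs|})/(B + 1), never exactly 0 and never below
1/(B + 1); the exact mode enumerates all distinct label assignments
(feasible at small n) and reproduces the exhaustive permutation
distribution. Comparisons use a 1e-12 tolerance so ties in |T| count as
exceedances rather than depending on float rounding.

## Concordance screening (`dtpkit.concordance`)

Profiles are ranked by differential-expression value descending, ties
broken by gene identifier, so screens are deterministic. The score is the
signed two-sided running-sum statistic: `a = maxⱼ(j/s − pⱼ/N)` measures
crowding of the signature toward the top of the ranking,
`b = maxⱼ(pⱼ/N − (j−1)/s)` toward the bottom, and the score is `a` if
`a ≥ b` (with 1e-12 tie tolerance) else `−b`. Ties resolve to the
positive branch so a contiguous block at the top scores exactly
`1 − s/N` and at the bottom `−(1 − (s−1)/N)` for every s < N; the sign at
an exact tie is pure convention. Two discrete-statistic facts worth
knowing: reversing a ranking maps a score `a` to `−(a + 1/N)` (a
step-function offset, not exact negation), and both orientations can
score negative in the narrow band `a < b < a + 2/N`.

The null is the score distribution of random gene sets of the signature's
size. Because a random set occupies uniformly random positions in any
fixed ranking, the null depends only on (N, s) and one seeded sample of R
scores serves the whole screen. Empirical p-values are two-sided on |score|
with the add-one estimator; BH runs across all perturbations. When
selecting hits, note the p floor 1/(R + 1): R must be large enough that
the floor clears α/(number of perturbations) after BH, or no single hit
can reach significance regardless of effect size (the default R = 1000
suits screens of up to ~50 perturbations; the examples use larger R for
larger screens). Signature genes absent from the reference universe are
dropped with their count recorded on the result, mirroring the
platform-intersection step a real screen requires. Reversal candidates
are records with score < 0 and q ≤ α, optionally restricted to annotated
perturbagens, sorted most-negative-first with identifier tie-breaks.

## Image quantification (`dtpkit.imaging`)

Segmentation is a fixed, fully specified chain: Otsu global threshold on
the nuclear channel, binary hole filling, 8-connected labeling, removal
of components with area strictly below `min_area` (default 50 px),
sequential relabeling. A constant image yields zero nuclei rather than an
error. Integrated density is the raw sum of protein-channel values over a
nucleus's pixels — no background subtraction by default, matching the
raw-sum definition of integrated density; the relative integrated density
divides by the mean integrated density of a control image's nuclei. The
chain has no watershed splitting, z-stack handling or illumination
correction; on synthetic images with separated disks and SNR ≥ 5 it
recovers every planted nucleus with integrated densities within 10% of
truth, which is the regime it is intended for.

## Problem sizes

The validation suite and the reproduction script run at the scales the
methods are designed for while staying desk-sized: whitelisting is
exercised at 500 true barcodes × 200,000 reads × 20 replicates (and 50 ×
100,000 × 10 in unit tests); the concordance null-control check uses 200
pure-noise perturbations × 20 seeds at R = 1000; expression simulations
use 2,000 genes for p-value-uniformity checks and 100–300 genes for
recovery checks; images are 128–256 px square with 3–12 nuclei. These
sizes were chosen so each statistical property is measured with adequate
Monte Carlo resolution.
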