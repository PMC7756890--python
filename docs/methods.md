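# Methods

## Signature selection

The selection operates on raw read counts of a clustered scRNA-seq data
set. For each gene the package computes, relative to the designated target
cluster: total reads over all cells considered, reads inside the target
cluster, the cluster read fraction, and the minimum read count over
target-cluster cells that express the gene. A gene is selected when the
fraction strictly exceeds the threshold (default 0.70), the in-cluster
cumulative reads strictly exceed 100, and every expressing in-cluster cell
carries at least 2 reads. The boundary senses (strict, strict, inclusive)
are part of the contract and are covered by boundary tests.

Conventions for degenerate cases: a gene with zero total reads has
fraction 0 (avoiding 0/0, and it fails the cumulative criterion anyway);
a gene with no expressing cell in the target cluster is never selected,
even under degenerate thresholds — a signature gene must be observed in the
cluster it is supposed to mark. Fractions are compared as exact
`cluster_reads / total_reads` floats; one-decimal percentages are
display-only. Output order is cluster fraction descending with ties broken
by gene ID ascending, so results are deterministic.

Restricting the cells used (e.g. to one donor group, as when the rare type
is nearly absent in controls) is exposed as a barcode-subset argument on
the statistics computation rather than hard-coded donor logic; all three
criteria are computed on the same (possibly subset) cell set.

## Composite score

`score(s) = Σ_g log2(FPKM[g,s] + pseudocount)` over the signature genes
present in the bulk matrix. FPKM is computed as
`counts · 1e9 / (length_bp · library_size)`; lowly expressed genes are
deliberately not filtered, since the signal of a rare cell type lives in
the low-expression range. The pseudocount (default 1) keeps the score
defined at FPKM 0 and bounded below by 0; how zeros were handled in the
original analysis is not recoverable, so the default is documented here as
this package's choice, not asserted as anyone else's. Signature genes
missing from the bulk matrix are skipped and reported (a data-integration
gap is not evidence of absence); a strict mode errors instead. Scores are
sums by default; a mean mode divides by the number of genes used for
comparability across signature sizes.

## Validation statistics

Pearson r uses the product-moment formula with a two-sided p from the t
distribution (n − 2 df); samples without a reference count are dropped and
counted. FDR is Benjamini-Hochberg step-up applied across the family of
signatures validated in one call (e.g. a 0.70/0.75/0.80 sweep); the family
size is logged and reported. Note the step-up is not idempotent — only
constant q-vectors are fixed points — so q-values are computed exactly once
per family.

Mann-Whitney U is two-sided throughout. With ≤ 12 pooled observations and
no ties the p-value is computed by full enumeration of all C(n, n1) rank
assignments; otherwise midranks are used with the tie-corrected normal
variance and a 0.5 continuity correction. Exact mode refuses ties and falls
back to the approximation with a warning. Because "median ± x" notation is
ambiguous, group summaries report median, SD and MAD side by side and leave
the choice of dispersion measure to the reader.

## NNLS baseline

The reference matrix takes, per cluster, the top genes by that cluster's
read fraction (reusing the same statistic as the signature selection, which
keeps the comparator deterministic and self-contained), forms per-cluster
mean count profiles over the union of selections, and scales each profile —
and each bulk sample — to counts-per-10k so units match. Proportions are
obtained by solving `min ‖Ax − b‖₂, x ≥ 0` (Lawson-Hanson active set via
`scipy.optimize.nnls`) and normalizing to sum 1 after the fit, following
common deconvolution practice; an all-zero solution is flagged degenerate
rather than normalized.

## Synthetic-data generator

The generator emulates the regime the method targets: ~5000 cells across
six clusters with proportions mirroring a bronchial biopsy (92% epithelial
down to a 0.2% rare cluster), 2000 genes, and negative-binomial
(gamma-Poisson) counts with size parameter 2 — the standard overdispersion
model for scRNA-seq. Baseline per-gene means are lognormal (σ = 1), scaled
so a cell averages `depth_per_cell` (default 2000) reads.

Each cluster gets `markers_per_cluster` (default 15) planted markers with
in-cluster mean `marker_fold × depth_per_cell / n_genes` (default 50 → 50
counts/cell) and a near-zero off-cluster mean `marker_leakage` (default
0.01 counts/cell). The fold is expressed against the average background
gene rather than per-gene baseline because a 0.2% cluster can only dominate
a gene's reads when off-cluster expression is close to zero: with ~10 rare
cells the expected cluster read fraction of a rare marker is
`10·50 / (10·50 + 4990·0.01) ≈ 0.91`, comfortably above the 0.70 criterion,
while background genes sit near the cluster's cell share (~0.002). This is
what makes end-to-end marker recovery a sharp test rather than a borderline
one.

Pseudo-bulk samples draw a rare fraction uniformly from
`rare_fraction_range`, mix the true per-cluster mean profiles at the
implied weights, multiply per gene by a unit-mean lognormal
biological-variability factor (`bulk_bio_cv`, default 0.4 — bulk cohorts of
distinct subjects do not share one expression profile, and omitting this
term makes deconvolution against the generating profiles unrealistically
easy), and draw observed counts multinomially at `bulk_depth` (default
10⁶). Gene lengths are uniform on 200–10 000 bp so the FPKM path is
exercised. Mixing mean profiles rather than resampling cells gives exact
control of the true fraction, which is what the benchmarks correlate
against.

Reference cell counts are `round(truth · area_scale · lognormal noise)`
with CV `ihc_noise_cv` (default 0.3) — a stand-in for stained-section cell
counting, which shares the biopsy but not the measurement error of the
sequencing. A two-group label with a multiplicative shift on truth (treated
< untreated when shift < 1) emulates a treatment effect in the direction
observed for inhaled corticosteroids.

All randomness derives from one seed through fixed `SeedSequence` child
streams (single-cell, bulk, reference counts), so each stage reproduces
bit-identically regardless of call order; simulation runs echo their full
config as JSON.

### What the synthetic data does not model

Ambient RNA, doublets, donor-level batch effects, platform mismatch between
the single-cell reference and the bulk assay, cluster-specific expression
of non-marker genes, and length bias in the single-cell protocol. Passing
the synthetic benchmarks therefore demonstrates correctness of the
computations and the qualitative rare-type behaviour of the estimators, not
performance on real biopsies; the published cohort correlation (r ≈ 0.4)
is far below the synthetic one because real data carry all of the above.

## Problem sizes and numerical choices

Default benchmark sizes — 5000 cells × 2000 genes, 40 pseudo-bulk samples,
20 simulation seeds for recovery, 500 null replicates for calibration, 1000
replicates for power — were chosen as the smallest sizes at which the
quantities of interest are stable to well within the asserted margins.
Tolerances: exact equality for integer outputs and rank-based p-values at
small n; 1e−12 for closed-form correlation checks; 1e−8 for noiseless NNLS
mixture recovery. Orientation of Matrix Market input is auto-detected from
the identifier files and refuses to guess when gene and barcode counts
coincide. Missing values in bulk tables are an error, never imputed.

## Known limitations

The composite score is a transcript-abundance index, not a calibrated
proportion; scores are comparable within one cohort and signature but not
across signatures of different sizes (use the mean mode for that). The
exact Mann-Whitney path enumerates combinations and is intended for the
small-sample regime only. FPKM is the only supported bulk unit by design;
TPM/CPM and cross-sample normalization are out of scope.
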