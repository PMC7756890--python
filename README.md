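# raresig

Quantify a **rare cell type** in bulk RNA-seq using a gene signature derived
from clustered single-cell RNA-seq counts.

Bulk RNA-seq averages over every cell in a tissue sample, so the
contribution of a rare population — mast cells in bronchial biopsies are the
motivating example, at ~0.2% of cells — is buried under the dominant cell
types. Reference-based deconvolution (CIBERSORT, NNLS) is designed for the
major populations and becomes unreliable at such frequencies. `raresig`
implements the alternative: select genes whose reads come almost exclusively
from the rare cluster in a small scRNA-seq data set, then summarize their
expression in each bulk sample as a single composite score.

## Method

Given a gene × cell count matrix with cluster labels and a designated target
cluster, a gene g enters the signature when

* **(a)** its cluster read fraction exceeds a threshold *t* (default 0.70):
  `reads(g, target cluster) / reads(g, all cells) > t`;
* **(b)** its cumulative reads inside the target cluster exceed 100 (strict);
* **(c)** every target-cluster cell expressing g contributes ≥ 2 reads
  (dropout cells with zero reads are allowed).

Raising *t* (0.70 → 0.75 → 0.80) shrinks the signature monotonically; the
three thresholds are one parameterized code path.

For a bulk sample *s* the **composite score** is

```
score(s) = Σ_{g ∈ signature} log2(FPKM[g, s] + 1)
```

with `FPKM[g,s] = counts[g,s] · 10⁹ / (length_bp[g] · library_size[s])`
computed on demand from raw counts. The score is validated against
per-sample orthogonal cell counts (Pearson r with a t-based p-value,
Benjamini-Hochberg FDR across the signature family) and compared between
sample groups with a two-sided Mann-Whitney U test (exact enumeration for
small tie-free problems, tie-corrected normal approximation otherwise).

The package also ships an **NNLS deconvolution baseline** (cluster-mean
reference profiles over fraction-ranked marker genes, counts-per-10k
scaling) and a **synthetic-data generator** — negative-binomial scRNA-seq
counts with planted markers, pseudo-bulk mixtures at exactly known
rare-cell fractions, and noisy reference cell counts — so the full pipeline
is benchmarked against ground truth at desk scale.

## Worked example

Simulate a study (5000 cells, 2000 genes, rare cluster at 0.2%, 40
pseudo-bulk samples), derive the signature, score the bulk samples and
validate against the noisy reference counts:

```bash
cat > sim.yaml <<EOF
n_cells: 5000
n_genes: 2000
seed: 7
EOF
raresig simulate --config sim.yaml --out-dir sim
raresig derive-signature --mtx sim/matrix.mtx --genes sim/genes.tsv \
    --barcodes sim/barcodes.tsv --clusters sim/clusters.tsv \
    --target-cluster mast --out signature.tsv
raresig score --bulk sim/bulk_counts.tsv --value-kind counts \
    --lengths sim/gene_lengths.tsv --signature signature.tsv --out scores.tsv
raresig validate --scores scores.tsv --meta sim/meta.tsv --out validation.json
```

This prints `signature of 15 gene(s) written to signature.tsv` — all 15
planted rare-cluster markers, no false positives. The signature table ranks
genes by cluster read fraction:

```
gene    cluster_fraction    cluster_reads   total_reads
g01028  0.9498289623717218  833             877
g01682  0.9458064516129032  733             775
g00242  0.9430555555555555  679             720
...
```

`scores.tsv` holds one composite score per sample (e.g. `sample000 111.72`,
`sample001 72.67` — higher score, more rare-cell transcript), and
`validation.json` reports the agreement with the reference counts:

```json
"scores": { "n": 40, "pearson_r": 0.869, "p_value": 3.7e-13, "q_value": 3.7e-13 }
```

i.e. across 40 samples the score explains the simulated cell counts well
(r = 0.87), with the q-value equal to p here because only one signature was
validated. A `raresig deconvolve` subcommand produces the NNLS cell-type
proportion estimates for comparison, and every run writes a manifest
(version, parameters, input checksums, seed) next to its output.

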