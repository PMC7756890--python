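"""Non-negative least squares (NNLS) bulk deconvolution baseline.

The reference signature matrix is built from the clustered single-cell
counts themselves: for each cluster, the top genes by that cluster's read
fraction are pooled, and per-cluster mean expression over the pooled gene
set forms the profile matrix.  Both the profiles and each bulk sample are
scaled to counts-per-10k before fitting so that units match.  This is a
deterministic, self-contained comparator for the composite score; it is the
standard approach for estimating proportions of common cell types and is
expected to degrade for very rare ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .io_formats import BulkMatrix, ClusterLabels, ScCounts
from .sc_signature import compute_gene_stats

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureMatrix",
    "DeconvResult",
    "build_signature_matrix",
    "nnls_deconvolve",
    "deconvolve_bulk",
]

_CP10K = 1e4


@dataclass
class SignatureMatrix:
    """Gene × cell-type reference profiles (counts-per-10k scale)."""

    genes: list[str]
    cell_types: list[str]
    profiles: np.ndarray

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (len(self.genes), len(self.cell_types)):
            raise ValueError("profile matrix shape does not match gene/type lists")
        if self.profiles.size and self.profiles.min() < 0:
            raise ValueError("negative value in signature matrix")
        if self.profiles.size and (self.profiles.sum(axis=0) == 0).any():
            raise ValueError("all-zero cell-type column in signature matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.profiles, index=self.genes, columns=self.cell_types)


@dataclass(frozen=True)
class DeconvResult:
    """Proportion estimate for one bulk sample."""

    proportions: pd.Series  # cell type -> proportion (sums to 1 unless degenerate)
    coefficients: pd.Series  # raw NNLS solution before normalization
    residual: float  # ||A x - b||_2
    degenerate: bool  # all-zero NNLS solution; proportions left at zero


def build_signature_matrix(
    counts: ScCounts,
    labels: ClusterLabels,
    genes_per_cluster: int,
) -> SignatureMatrix:
    """Cluster-mean reference profiles over fraction-ranked marker genes.

    For every cluster, the ``genes_per_cluster`` genes with the highest read
    fraction in that cluster (ties broken by gene ID) are selected; the
    profile matrix is the per-cluster mean count vector, scaled to
    counts-per-10k per cell type, restricted to the union of selections.
    """
    if genes_per_cluster < 1:
        raise ValueError("genes_per_cluster must be >= 1")
    clusters = labels.clusters
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters to deconvolve")
    cell_clusters = labels.labels_for(counts.cells)

    k = min(genes_per_cluster, counts.n_genes)
    selected: set[str] = set()
    for cluster in clusters:
        stats = compute_gene_stats(counts, labels, target_cluster=cluster)
        if int(stats.table["cluster_reads"].sum()) == 0:
            raise ValueError(f"cluster {cluster!r} has zero total reads")
        top = stats.table.sort_values(
            by=["cluster_fraction", "gene"],
            ascending=[False, True],
            kind="mergesort",
        ).head(k)
        selected.update(top.index)
    union = sorted(selected)
    gene_idx = {g: i for i, g in enumerate(counts.genes)}
    rows = [gene_idx[g] for g in union]

    profiles = np.zeros((len(union), len(clusters)))
    for j, cluster in enumerate(clusters):
        in_cluster = cell_clusters == cluster
        mean_full = np.asarray(
            counts.counts[:, in_cluster].mean(axis=1)
        ).ravel()
        total = mean_full.sum()
        profiles[:, j] = mean_full[rows] / total * _CP10K
    return SignatureMatrix(genes=union, cell_types=list(clusters), profiles=profiles)


def nnls_deconvolve(
    bulk_sample: Sequence[float],
    sig: SignatureMatrix,
) -> DeconvResult:
    """Solve min ||A x - b|| s.t. x >= 0, then normalize x to proportions.

    An all-zero solution (e.g. b = 0) is returned as-is with the degenerate
    flag set instead of being normalized.
    """
    b = np.asarray(bulk_sample, dtype=float)
    if b.shape != (len(sig.genes),):
        raise ValueError(
            f"bulk vector length {b.shape} does not match "
            f"{len(sig.genes)} signature genes"
        )
    if b.size and b.min() < 0:
        raise ValueError("negative value in bulk vector")
    x, rnorm = scipy.optimize.nnls(sig.profiles, b)
    total = x.sum()
    degenerate = total == 0
    props = x.copy() if degenerate else x / total
    types = pd.Index(sig.cell_types, name="cell_type")
    return DeconvResult(
        proportions=pd.Series(props, index=types),
        coefficients=pd.Series(x, index=types),
        residual=float(rnorm),
        degenerate=degenerate,
    )


def deconvolve_bulk(bulk: BulkMatrix, sig: SignatureMatrix) -> pd.DataFrame:
    """Deconvolve every sample of a raw-count bulk matrix.

    Each sample is scaled to counts-per-10k over the full bulk gene set, then
    restricted to the signature genes.  All signature genes must be present.
    Returns a sample × cell-type proportion table with a ``degenerate``
    indicator column.
    """
    gene_idx = {g: i for i, g in enumerate(bulk.genes)}
    missing = [g for g in sig.genes if g not in gene_idx]
    if missing:
        raise ValueError(
            f"{len(missing)} signature gene(s) missing from bulk matrix, "
            f"first: {missing[0]!r}"
        )
    totals = bulk.values.sum(axis=0)
    if (totals == 0).any():
        bad = bulk.samples[int(np.argmin(totals))]
        raise ValueError(f"sample {bad!r} has zero total expression")
    rows = [gene_idx[g] for g in sig.genes]
    out = []
    for j, sample in enumerate(bulk.samples):
        b = bulk.values[rows, j] / totals[j] * _CP10K
        res = nnls_deconvolve(b, sig)
        rec = res.proportions.to_dict()
        rec["degenerate"] = res.degenerate
        out.append(rec)
    frame = pd.DataFrame(out, index=pd.Index(bulk.samples, name="sample"))
    return frame[sig.cell_types + ["degenerate"]]
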