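"""Derivation of a rare-cell-type gene signature from clustered scRNA-seq counts.

A gene enters the signature when three criteria hold, all computed on raw
read counts:

(a) more than ``fraction_threshold`` (default 70%) of all reads of the gene,
    over every cell considered, map to cells of the target cluster;
(b) the cumulative number of reads for the gene inside the target cluster
    exceeds ``min_cumulative_reads`` (default 100, strict);
(c) every target-cluster cell that expresses the gene at all contributes at
    least ``min_reads_per_expressing_cell`` reads (default 2); dropout cells
    with zero reads are tolerated.

The fraction threshold is the tunable stringency knob: raising it from 0.70
shrinks the signature monotonically (higher-threshold signatures are nested
inside lower-threshold ones when (b) and (c) are held fixed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import ClusterLabels, ScCounts

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureCriteria",
    "GeneStats",
    "SignatureEntry",
    "GeneSignature",
    "compute_gene_stats",
    "derive_signature",
    "signature_threshold_sweep",
    "write_signature",
    "read_signature",
]

#: columns every GeneStats table must carry
_STAT_COLUMNS = (
    "total_reads",
    "cluster_reads",
    "cluster_fraction",
    "min_expressing_read",
    "n_expressing_cells",
)


@dataclass(frozen=True)
class SignatureCriteria:
    """Thresholds of the three selection criteria.

    ``fraction_threshold`` is strict (>), ``min_cumulative_reads`` is strict
    (>), ``min_reads_per_expressing_cell`` is inclusive (>=) — exactly the
    senses in which the criteria are stated.
    """

    fraction_threshold: float = 0.70
    min_cumulative_reads: int = 100
    min_reads_per_expressing_cell: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_threshold < 1.0:
            raise ValueError("fraction_threshold must lie in the open interval (0, 1)")
        if self.min_cumulative_reads < 0:
            raise ValueError("min_cumulative_reads must be non-negative")
        if self.min_reads_per_expressing_cell < 1:
            raise ValueError("min_reads_per_expressing_cell must be positive")


@dataclass
class GeneStats:
    """Per-gene read statistics relative to one target cluster.

    ``table`` is indexed by gene with columns ``total_reads``,
    ``cluster_reads``, ``cluster_fraction`` (0 when total_reads is 0),
    ``min_expressing_read`` (NaN when no target-cluster cell expresses the
    gene) and ``n_expressing_cells``.
    """

    table: pd.DataFrame
    target_cluster: str

    def __post_init__(self) -> None:
        missing = [c for c in _STAT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"GeneStats table missing columns: {missing}")
        frac = self.table["cluster_fraction"]
        if ((frac < 0) | (frac > 1)).any():
            raise ValueError("cluster_fraction outside [0, 1]")
        if (self.table["cluster_reads"] > self.table["total_reads"]).any():
            raise ValueError("cluster_reads exceeds total_reads")


@dataclass(frozen=True)
class SignatureEntry:
    gene: str
    cluster_fraction: float
    cluster_reads: int
    total_reads: int


@dataclass
class GeneSignature:
    """Ordered gene signature: fraction descending, ties by gene ID ascending."""

    entries: list[SignatureEntry]
    criteria: Optional[SignatureCriteria] = None

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.gene, e.cluster_fraction, e.cluster_reads, e.total_reads)
                for e in self.entries
            ],
            columns=["gene", "cluster_fraction", "cluster_reads", "total_reads"],
        )


def compute_gene_stats(
    counts: ScCounts,
    labels: ClusterLabels,
    cell_subset: Optional[Iterable[str]] = None,
    target_cluster: Optional[str] = None,
) -> GeneStats:
    """Compute per-gene totals, target-cluster reads and read fractions.

    ``cell_subset`` restricts every statistic (all three criteria alike) to
    the named barcodes — e.g. cells from one donor group.  ``target_cluster``
    overrides the cluster designated in ``labels``; this lets a caller reuse
    the routine for each cluster in turn.
    """
    target = labels.target_cluster if target_cluster is None else target_cluster
    cells = counts.cells
    mat = counts.counts
    if cell_subset is not None:
        subset = set(cell_subset)
        unknown = subset - set(cells)
        if unknown:
            raise ValueError(
                f"cell subset names {len(unknown)} unknown barcode(s), "
                f"first: {sorted(unknown)[0]!r}"
            )
        keep = np.array([c in subset for c in cells])
        cells = [c for c, k in zip(cells, keep) if k]
        mat = mat[:, keep]
    cell_clusters = labels.labels_for(cells)
    in_target = cell_clusters == target

    total_reads = np.asarray(mat.sum(axis=1)).ravel()
    target_mat = mat[:, in_target].tocsr()
    cluster_reads = np.asarray(target_mat.sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = np.where(total_reads > 0, cluster_reads / np.maximum(total_reads, 1), 0.0)

    # per-row minimum over stored nonzeros of the target-cluster submatrix
    n_genes = mat.shape[0]
    min_expr = np.full(n_genes, np.nan)
    n_expr = np.diff(target_mat.indptr)
    rows = np.flatnonzero(n_expr)
    if rows.size:
        mins = np.minimum.reduceat(target_mat.data, target_mat.indptr[rows])
        min_expr[rows] = mins

    table = pd.DataFrame(
        {
            "total_reads": total_reads.astype(np.int64),
            "cluster_reads": cluster_reads.astype(np.int64),
            "cluster_fraction": fraction,
            "min_expressing_read": min_expr,
            "n_expressing_cells": n_expr.astype(np.int64),
        },
        index=pd.Index(counts.genes, name="gene"),
    )
    return GeneStats(table=table, target_cluster=target)


def derive_signature(
    stats: GeneStats,
    criteria: SignatureCriteria = SignatureCriteria(),
) -> GeneSignature:
    """Select the genes satisfying all three criteria, in deterministic order.

    A gene with no expressing cell in the target cluster is never selected,
    even under degenerate criteria settings: a signature gene must be
    observed in the target cluster at all.
    """
    tab = stats.table
    if tab.empty:
        raise ValueError("gene statistics table is empty")
    mask = (
        (tab["cluster_fraction"] > criteria.fraction_threshold)
        & (tab["cluster_reads"] > criteria.min_cumulative_reads)
        & (tab["n_expressing_cells"] > 0)
        & (tab["min_expressing_read"] >= criteria.min_reads_per_expressing_cell)
    )
    selected = tab[mask.fillna(False)]
    order = selected.sort_values(
        by=["cluster_fraction", "gene"],
        ascending=[False, True],
        kind="mergesort",
    )
    entries = [
        SignatureEntry(
            gene=str(gene),
            cluster_fraction=float(row["cluster_fraction"]),
            cluster_reads=int(row["cluster_reads"]),
            total_reads=int(row["total_reads"]),
        )
        for gene, row in order.iterrows()
    ]
    if not entries:
        logger.warning(
            "no gene passed the selection criteria (threshold %.3f); "
            "signature is empty",
            criteria.fraction_threshold,
        )
    return GeneSignature(entries=entries, criteria=criteria)


def signature_threshold_sweep(
    stats: GeneStats,
    thresholds: Sequence[float],
    criteria_base: SignatureCriteria = SignatureCriteria(),
) -> list[tuple[float, GeneSignature]]:
    """Re-derive the signature at each fraction threshold, (b) and (c) fixed."""
    out = []
    for t in thresholds:
        crit = SignatureCriteria(
            fraction_threshold=t,
            min_cumulative_reads=criteria_base.min_cumulative_reads,
            min_reads_per_expressing_cell=criteria_base.min_reads_per_expressing_cell,
        )
        out.append((t, derive_signature(stats, crit)))
    return out


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    sig.to_frame().to_csv(path, sep="\t", index=False)


def read_signature(path: str | Path) -> GeneSignature:
    frame = pd.read_csv(path, sep="\t")
    required = {"gene", "cluster_fraction", "cluster_reads", "total_reads"}
    if not required.issubset(frame.columns):
        raise ValueError(f"signature file must have columns {sorted(required)}")
    entries = [
        SignatureEntry(
            gene=str(r.gene),
            cluster_fraction=float(r.cluster_fraction),
            cluster_reads=int(r.cluster_reads),
            total_reads=int(r.total_reads),
        )
        for r in frame.itertuples()
    ]
    return GeneSignature(entries=entries)
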