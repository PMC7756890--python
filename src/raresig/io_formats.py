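"""Readers and writers for every external file the pipeline touches.

All on-disk formats are plain text: Matrix Market coordinate files plus
gene/barcode TSVs for single-cell counts (10x CellRanger layout accepted),
and tab-delimited tables for cluster labels, bulk expression, gene lengths,
sample metadata and gene signatures.  Every reader validates its input and
returns a typed in-memory object; downstream modules never touch files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "ScCounts",
    "ClusterLabels",
    "BulkMatrix",
    "SampleMeta",
    "read_sc_counts",
    "write_sc_counts",
    "read_cluster_labels",
    "write_cluster_labels",
    "read_bulk",
    "write_bulk",
    "read_sample_meta",
    "write_sample_meta",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class ScCounts:
    """Sparse gene × cell read-count matrix with row/column identifiers.

    ``counts`` is stored CSR (genes as rows).  Entries are non-negative
    integers; gene identifiers and cell barcodes are unique opaque strings.
    """

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        _check_unique(self.genes, "gene")
        _check_unique(self.cells, "cell barcode")
        data = self.counts.data
        if data.size and not np.all(data == np.floor(data)):
            raise ValueError("non-integer count encountered")
        if data.size and data.min() < 0:
            raise ValueError("negative count encountered")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class ClusterLabels:
    """Barcode → cluster assignment with one designated target cluster."""

    assignment: dict[str, str]
    target_cluster: str

    def __post_init__(self) -> None:
        if self.target_cluster not in set(self.assignment.values()):
            raise ValueError(
                f"target cluster {self.target_cluster!r} has no labelled cells"
            )

    @property
    def clusters(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def labels_for(self, cells: Sequence[str]) -> np.ndarray:
        """Cluster label per barcode, erroring on any unlabelled barcode."""
        missing = [c for c in cells if c not in self.assignment]
        if missing:
            raise ValueError(
                f"{len(missing)} barcode(s) without a cluster label, "
                f"first: {missing[0]!r}"
            )
        return np.array([self.assignment[c] for c in cells], dtype=object)


@dataclass
class BulkMatrix:
    """Gene × sample bulk expression, either FPKM or raw counts.

    When ``value_kind == "raw_counts"`` a strictly positive per-gene length
    vector (base pairs, aligned with ``genes``) is required for later FPKM
    conversion.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    value_kind: str
    gene_lengths: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.value_kind not in ("fpkm", "raw_counts"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"bulk matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        _check_unique(self.genes, "gene")
        _check_unique(self.samples, "sample")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite or missing bulk value encountered")
        if self.values.size and self.values.min() < 0:
            raise ValueError("negative bulk value encountered")
        if self.value_kind == "raw_counts":
            if self.gene_lengths is None:
                raise ValueError("raw_counts bulk matrix requires gene_lengths")
        if self.gene_lengths is not None:
            self.gene_lengths = np.asarray(self.gene_lengths, dtype=float)
            if self.gene_lengths.shape != (len(self.genes),):
                raise ValueError("gene_lengths must align with genes")
            if np.any(self.gene_lengths <= 0):
                bad = self.genes[int(np.argmin(self.gene_lengths))]
                raise ValueError(f"non-positive length for gene {bad!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class SampleMeta:
    """Per-sample reference cell count and optional group label.

    ``table`` is indexed by sample ID with columns ``cell_count`` (float,
    NaN = missing) and ``group`` (object, NaN = missing).  Whether the
    samples match a companion :class:`BulkMatrix` is checked at join time,
    not here.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        tab = self.table.copy()
        for col in ("cell_count", "group"):
            if col not in tab.columns:
                tab[col] = np.nan
        if tab.index.has_duplicates:
            raise ValueError("duplicate sample ID in metadata")
        counts = pd.to_numeric(tab["cell_count"], errors="raise")
        if (counts.dropna() < 0).any():
            raise ValueError("negative cell_count in metadata")
        tab["cell_count"] = counts.astype(float)
        self.table = tab[["cell_count", "group"]]

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)


# ---------------------------------------------------------------------------
# single-cell counts (Matrix Market + gene/barcode TSVs)
# ---------------------------------------------------------------------------

def _read_id_column(path: str | Path, what: str) -> list[str]:
    # 10x features.tsv may carry extra columns (symbol, feature type); only
    # the first column is the identifier.
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    ids = frame.iloc[:, 0].tolist()
    if any(i is None or (isinstance(i, float) and np.isnan(i)) for i in ids):
        raise ValueError(f"empty {what} identifier in {path}")
    return ids


def read_sc_counts(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> ScCounts:
    """Read a Matrix Market count file with companion gene/barcode TSVs.

    Orientation is auto-detected by matching the matrix dimensions against
    the lengths of the two identifier files; a square case where both
    interpretations fit raises rather than guessing.
    """
    genes = _read_id_column(genes_path, "gene")
    barcodes = _read_id_column(barcodes_path, "barcode")
    mat = sp.coo_matrix(scipy.io.mmread(str(mtx_path)))
    n_rows, n_cols = mat.shape

    genes_by_row = n_rows == len(genes) and n_cols == len(barcodes)
    genes_by_col = n_rows == len(barcodes) and n_cols == len(genes)
    if genes_by_row and genes_by_col:
        raise ValueError(
            "orientation ambiguous: gene count equals barcode count "
            f"({len(genes)}); refusing to guess"
        )
    if genes_by_col and not genes_by_row:
        mat = mat.T
    elif not genes_by_row:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither {len(genes)} genes x "
            f"{len(barcodes)} barcodes nor its transpose"
        )
    if mat.data.size and not np.all(mat.data == np.floor(mat.data)):
        raise ValueError("non-integer count in MTX file")
    if mat.data.size and mat.data.min() < 0:
        raise ValueError("negative count in MTX file")
    return ScCounts(genes=genes, cells=barcodes, counts=mat.tocsr())


def write_sc_counts(
    sc: ScCounts,
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write counts in the gene × cell orientation with integer field."""
    scipy.io.mmwrite(str(mtx_path), sc.counts.tocoo(), field="integer")
    Path(genes_path).write_text("".join(f"{g}\n" for g in sc.genes))
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in sc.cells))


# ---------------------------------------------------------------------------
# cluster labels
# ---------------------------------------------------------------------------

def read_cluster_labels(
    tsv_path: str | Path,
    target_cluster: str,
    header: bool = False,
) -> ClusterLabels:
    """Read a two-column (barcode, cluster) TSV."""
    frame = pd.read_csv(
        tsv_path, sep="\t", header=0 if header else None, dtype=str
    )
    if frame.shape[1] < 2:
        raise ValueError("cluster label file needs two columns: barcode, cluster")
    barcodes = frame.iloc[:, 0]
    if barcodes.duplicated().any():
        dup = barcodes[barcodes.duplicated()].iloc[0]
        raise ValueError(f"barcode labelled twice: {dup!r}")
    assignment = dict(zip(barcodes, frame.iloc[:, 1]))
    return ClusterLabels(assignment=assignment, target_cluster=target_cluster)


def write_cluster_labels(labels: ClusterLabels, tsv_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        for barcode, cluster in labels.assignment.items():
            fh.write(f"{barcode}\t{cluster}\n")


# ---------------------------------------------------------------------------
# bulk expression
# ---------------------------------------------------------------------------

def _read_lengths(lengths_path: str | Path, genes: Sequence[str]) -> np.ndarray:
    frame = pd.read_csv(lengths_path, sep="\t", header=None, dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("gene length file needs two columns: gene, length_bp")
    series = pd.Series(
        pd.to_numeric(frame.iloc[:, 1]).values, index=frame.iloc[:, 0]
    )
    if series.index.has_duplicates:
        raise ValueError("duplicate gene in length file")
    missing = [g for g in genes if g not in series.index]
    if missing:
        raise ValueError(
            f"{len(missing)} bulk gene(s) without a length, first: {missing[0]!r}"
        )
    return series.reindex(genes).to_numpy(dtype=float)


def read_bulk(
    tsv_path: str | Path,
    value_kind: str,
    lengths_path: Optional[str | Path] = None,
) -> BulkMatrix:
    """Read a gene × sample TSV (header row = sample IDs, first column = gene)."""
    frame = pd.read_csv(tsv_path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicate gene in bulk table: {dup!r}")
    if frame.isna().any().any():
        raise ValueError("missing value in bulk table; imputation is not supported")
    lengths = None
    if value_kind == "raw_counts":
        if lengths_path is None:
            raise ValueError("value_kind=raw_counts requires a gene length file")
        lengths = _read_lengths(lengths_path, list(frame.index))
    return BulkMatrix(
        genes=[str(g) for g in frame.index],
        samples=[str(s) for s in frame.columns],
        values=frame.to_numpy(dtype=float),
        value_kind=value_kind,
        gene_lengths=lengths,
    )


def write_bulk(
    bulk: BulkMatrix,
    tsv_path: str | Path,
    lengths_path: Optional[str | Path] = None,
) -> None:
    bulk.to_frame().to_csv(tsv_path, sep="\t", index_label="gene")
    if lengths_path is not None:
        if bulk.gene_lengths is None:
            raise ValueError("bulk matrix carries no gene lengths to write")
        with open(lengths_path, "w") as fh:
            for gene, length in zip(bulk.genes, bulk.gene_lengths):
                fh.write(f"{gene}\t{length:g}\n")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_sample_meta(tsv_path: str | Path) -> SampleMeta:
    """Read a sample metadata TSV with header: sample, cell_count[, group]."""
    frame = pd.read_csv(tsv_path, sep="\t", index_col=0, dtype={0: str})
    frame.index = frame.index.astype(str)
    return SampleMeta(table=frame)


def write_sample_meta(meta: SampleMeta, tsv_path: str | Path) -> None:
    meta.table.to_csv(tsv_path, sep="\t", index_label="sample")
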