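"""FPKM conversion and the composite signature score for bulk samples.

The composite score of a sample is the sum, over the signature genes, of
log2(FPKM + pseudocount).  It is a transcript-abundance proxy for the rare
cell type's content of the sample, not a proportion estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .io_formats import BulkMatrix
from .sc_signature import GeneSignature

logger = logging.getLogger(__name__)

__all__ = ["ScoreTable", "counts_to_fpkm", "composite_score"]


@dataclass
class ScoreTable:
    """Per-sample composite score with provenance of how it was computed."""

    table: pd.DataFrame  # index: sample; columns: composite_score, n_genes_used
    genes_used: list[str]
    missing_genes: list[str]
    pseudocount: float

    @property
    def scores(self) -> pd.Series:
        return self.table["composite_score"]


def counts_to_fpkm(bulk: BulkMatrix) -> BulkMatrix:
    """Convert raw counts to FPKM: counts * 1e9 / (length_bp * library_size)."""
    if bulk.value_kind != "raw_counts":
        raise ValueError("counts_to_fpkm expects a raw_counts bulk matrix")
    totals = bulk.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"sample {bulk.samples[int(zero[0])]!r} has zero total counts"
        )
    fpkm = bulk.values * 1e9 / (bulk.gene_lengths[:, None] * totals[None, :])
    return BulkMatrix(
        genes=list(bulk.genes),
        samples=list(bulk.samples),
        values=fpkm,
        value_kind="fpkm",
        gene_lengths=bulk.gene_lengths.copy(),
    )


def composite_score(
    bulk: BulkMatrix,
    signature: Union[GeneSignature, Sequence[str]],
    pseudocount: float = 1.0,
    require_all_genes: bool = False,
    mean: bool = False,
) -> ScoreTable:
    """Sum of log2(FPKM + pseudocount) over the signature genes, per sample.

    Signature genes absent from the bulk matrix are skipped with a warning
    (a missing gene is a data-integration gap, not evidence of absence);
    ``require_all_genes`` turns that into an error.  ``mean`` divides by the
    number of genes used, for comparability across signature sizes.
    """
    if bulk.value_kind != "fpkm":
        raise ValueError(
            "composite_score expects FPKM values; convert counts first"
        )
    genes = list(signature.genes) if isinstance(signature, GeneSignature) else list(signature)
    if not genes:
        raise ValueError("empty signature")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")

    index = {g: i for i, g in enumerate(bulk.genes)}
    present = [g for g in genes if g in index]
    missing = [g for g in genes if g not in index]
    if not present:
        raise ValueError("no signature gene present in the bulk matrix")
    if missing:
        if require_all_genes:
            raise ValueError(
                f"{len(missing)} signature gene(s) missing from bulk matrix: "
                f"{missing}"
            )
        logger.warning(
            "%d signature gene(s) missing from bulk matrix, skipped: %s",
            len(missing),
            missing,
        )
    sub = bulk.values[[index[g] for g in present], :]
    if pseudocount == 0 and (sub == 0).any():
        raise ValueError("zero FPKM with pseudocount 0; log2 undefined")
    scores = np.log2(sub + pseudocount).sum(axis=0)
    if mean:
        scores = scores / len(present)
    table = pd.DataFrame(
        {
            "composite_score": scores,
            "n_genes_used": len(present),
        },
        index=pd.Index(bulk.samples, name="sample"),
    )
    return ScoreTable(
        table=table,
        genes_used=present,
        missing_genes=missing,
        pseudocount=pseudocount,
    )
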