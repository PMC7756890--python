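"""Synthetic scRNA-seq, pseudo-bulk and reference-count generator.

The generator emulates the data regime the pipeline is built for: a mixed
bronchial-biopsy-like cell population dominated by epithelial cells, with
one rare cluster (0.2% of cells by default, mirroring a mast-cell-sized
population), planted high-specificity marker genes per cluster,
negative-binomial (gamma-Poisson) counts, pseudo-bulk mixtures with exactly
known rare-cell fractions, and noisy per-sample reference cell counts that
stand in for immunohistochemical mast-cell counts.

Marker model: a marker of cluster k has per-cell NB mean
``marker_fold * depth_per_cell / n_genes`` inside k and ``marker_leakage``
(near-zero) in every other cluster.  With the defaults this puts a planted
rare-cluster marker's expected cluster read fraction around 0.9, so the
selection criteria recover planted markers while no background gene comes
near the threshold.

All randomness flows from ``SimConfig.seed`` through three fixed
``numpy.random.SeedSequence`` child streams (single-cell counts, bulk
mixtures, reference counts), so each stage is reproducible independently of
call order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import BulkMatrix, ClusterLabels, SampleMeta, ScCounts

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "ScSim", "simulate_sc", "simulate_bulk", "simulate_ihc"]

# cluster mix of the emulated tissue: dominant epithelium, a lymphocyte
# pool, minor structural populations and one rare cluster
_DEFAULT_CLUSTERS = (
    ("epithelial", 0.9219),
    ("lymphocyte", 0.0486),
    ("endothelial", 0.0214),
    ("fibroblast", 0.0059),
    ("smooth_muscle", 0.0022),
    ("mast", 0.0020),
)

_STREAM_SC, _STREAM_BULK, _STREAM_IHC = 0, 1, 2


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Proportions must sum to 1 (the defaults are normalized at construction);
    the rare cluster is the one named ``rare_cluster``.
    """

    n_cells: int = 5000
    n_genes: int = 2000
    cluster_names: tuple[str, ...] = tuple(n for n, _ in _DEFAULT_CLUSTERS)
    cluster_proportions: tuple[float, ...] = tuple(p for _, p in _DEFAULT_CLUSTERS)
    rare_cluster: str = "mast"
    markers_per_cluster: int = 15
    marker_fold: float = 50.0
    marker_leakage: float = 0.01  # off-cluster marker mean, counts per cell
    nb_dispersion: float = 2.0  # NB size parameter r; larger = less overdispersed
    depth_per_cell: int = 2000
    n_bulk_samples: int = 40
    rare_fraction_range: tuple[float, float] = (0.0, 0.05)
    bulk_depth: int = 1_000_000
    bulk_bio_cv: float = 0.4  # between-sample biological CV per gene
    ihc_area_scale: float = 5000.0  # cells counted per unit true fraction
    ihc_noise_cv: float = 0.3
    group_labels: tuple[str, str] = ("treated", "untreated")
    treated_fraction: float = 44 / 69
    group_shift: float = 1.0  # multiplier on truth for treated samples; <1 = lower
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cluster_names) != len(self.cluster_proportions):
            raise ValueError("cluster_names and cluster_proportions differ in length")
        props = np.asarray(self.cluster_proportions, dtype=float)
        if (props <= 0).any():
            raise ValueError("cluster proportions must be positive")
        object.__setattr__(
            self, "cluster_proportions", tuple(props / props.sum())
        )
        if self.rare_cluster not in self.cluster_names:
            raise ValueError(f"rare cluster {self.rare_cluster!r} not in cluster_names")
        for name, val in (
            ("n_cells", self.n_cells),
            ("n_genes", self.n_genes),
            ("markers_per_cluster", self.markers_per_cluster),
            ("depth_per_cell", self.depth_per_cell),
            ("n_bulk_samples", self.n_bulk_samples),
            ("bulk_depth", self.bulk_depth),
        ):
            if val < 1:
                raise ValueError(f"{name} must be positive")
        if self.markers_per_cluster * len(self.cluster_names) > self.n_genes:
            raise ValueError("not enough genes to host the requested markers")
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")
        if self.marker_leakage < 0 or self.nb_dispersion <= 0:
            raise ValueError("marker_leakage must be >= 0 and nb_dispersion > 0")
        lo, hi = self.rare_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("rare_fraction_range must satisfy 0 <= lo <= hi <= 1")
        if self.bulk_bio_cv < 0:
            raise ValueError("bulk_bio_cv must be >= 0")
        if self.ihc_noise_cv < 0 or self.ihc_area_scale <= 0:
            raise ValueError("invalid reference-count noise parameters")
        if not 0 < self.treated_fraction < 1:
            raise ValueError("treated_fraction must lie in (0, 1)")
        if self.group_shift <= 0:
            raise ValueError("group_shift must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScSim:
    """Output bundle of :func:`simulate_sc`."""

    counts: ScCounts
    labels: ClusterLabels
    markers: dict[str, list[str]]  # cluster -> planted marker genes
    mean_profiles: pd.DataFrame  # gene x cluster true per-cell NB means
    config: SimConfig


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    return np.random.default_rng(ss)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, r: float) -> np.ndarray:
    """Gamma-Poisson draw with mean `mean` and NB size r, elementwise."""
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = r / (r + mean[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def _mean_profiles(config: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    n_genes = config.n_genes
    clusters = list(config.cluster_names)
    genes = [f"g{i:05d}" for i in range(n_genes)]

    # lognormal baseline expression, scaled so a cell averages depth_per_cell
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)

    marker_genes = rng.choice(
        n_genes, size=config.markers_per_cluster * len(clusters), replace=False
    )
    markers: dict[str, list[str]] = {}
    profiles = np.tile(base[:, None], (1, len(clusters)))
    marker_mean = config.marker_fold * config.depth_per_cell / n_genes
    for j, cluster in enumerate(clusters):
        idx = marker_genes[
            j * config.markers_per_cluster : (j + 1) * config.markers_per_cluster
        ]
        profiles[idx, :] = config.marker_leakage
        profiles[idx, j] = marker_mean
        markers[cluster] = sorted(genes[i] for i in idx)

    # rescale non-marker baseline so each cluster's expected depth matches
    non_marker = np.ones(n_genes, dtype=bool)
    non_marker[marker_genes] = False
    for j in range(len(clusters)):
        marker_load = profiles[~non_marker, j].sum()
        budget = max(config.depth_per_cell - marker_load, 1.0)
        profiles[non_marker, j] *= budget / profiles[non_marker, j].sum()
    frame = pd.DataFrame(profiles, index=pd.Index(genes, name="gene"), columns=clusters)
    return frame, markers


def simulate_sc(config: SimConfig = SimConfig()) -> ScSim:
    """Simulate clustered single-cell counts with planted markers.

    Fixed seed gives bit-identical output.  Errors if the rare cluster
    receives no cells at the configured ``n_cells``.
    """
    rng = _rng(config, _STREAM_SC)
    clusters = list(config.cluster_names)
    profiles, markers = _mean_profiles(config, rng)

    membership = rng.choice(
        len(clusters), size=config.n_cells, p=np.asarray(config.cluster_proportions)
    )
    rare_idx = clusters.index(config.rare_cluster)
    n_rare = int((membership == rare_idx).sum())
    if n_rare == 0:
        raise ValueError(
            f"rare cluster {config.rare_cluster!r} received 0 of {config.n_cells} "
            "cells; increase n_cells or its proportion"
        )
    logger.info("rare cluster %r: %d cells", config.rare_cluster, n_rare)

    counts = np.zeros((config.n_genes, config.n_cells), dtype=np.int64)
    mean_mat = profiles.to_numpy()
    for j in range(len(clusters)):
        cols = np.flatnonzero(membership == j)
        if cols.size == 0:
            continue
        mean_block = np.broadcast_to(
            mean_mat[:, j][:, None], (config.n_genes, cols.size)
        )
        counts[:, cols] = _nb_draw(rng, np.ascontiguousarray(mean_block), config.nb_dispersion)

    barcodes = [f"cell{i:06d}" for i in range(config.n_cells)]
    sc = ScCounts(
        genes=list(profiles.index),
        cells=barcodes,
        counts=sp.csr_matrix(counts),
    )
    labels = ClusterLabels(
        assignment={b: clusters[m] for b, m in zip(barcodes, membership)},
        target_cluster=config.rare_cluster,
    )
    return ScSim(
        counts=sc, labels=labels, markers=markers, mean_profiles=profiles, config=config
    )


def simulate_bulk(
    profiles: Union[ScSim, pd.DataFrame],
    config: Optional[SimConfig] = None,
) -> tuple[BulkMatrix, pd.Series]:
    """Pseudo-bulk mixtures with exactly known rare-cell fractions.

    Per sample, the rare fraction is drawn uniformly from
    ``rare_fraction_range``; the remaining mass is split among the other
    clusters in proportion to their configured abundances.  The expected
    bulk profile is the fraction-weighted mixture of the true per-cluster
    mean profiles, modulated per sample and per gene by a unit-mean
    lognormal biological-variability factor (CV ``bulk_bio_cv``; real
    cohorts do not share one expression profile), and observed counts are
    multinomial at ``bulk_depth``.  Gene lengths (uniform 200-10000 bp) are
    attached so FPKM conversion is exercised downstream.

    Returns the raw-count bulk matrix and the true rare fraction per sample.
    """
    if isinstance(profiles, ScSim):
        if config is None:
            config = profiles.config
        profiles = profiles.mean_profiles
    if config is None:
        raise ValueError("config required when passing a bare profile table")
    rng = _rng(config, _STREAM_BULK)
    clusters = list(profiles.columns)
    rare_idx = clusters.index(config.rare_cluster)
    base = np.asarray(
        [config.cluster_proportions[config.cluster_names.index(c)] for c in clusters]
    )
    other = np.delete(base, rare_idx)
    other = other / other.sum()

    lo, hi = config.rare_fraction_range
    fractions = rng.uniform(lo, hi, size=config.n_bulk_samples)
    mean_mat = profiles.to_numpy()
    samples = [f"sample{i:03d}" for i in range(config.n_bulk_samples)]
    values = np.zeros((len(profiles), config.n_bulk_samples), dtype=float)
    if config.bulk_bio_cv > 0:
        sigma2 = math.log1p(config.bulk_bio_cv**2)
        bio = rng.lognormal(
            mean=-sigma2 / 2.0,
            sigma=math.sqrt(sigma2),
            size=(len(profiles), config.n_bulk_samples),
        )
    else:
        bio = np.ones((len(profiles), config.n_bulk_samples))
    for s, f in enumerate(fractions):
        w = np.empty(len(clusters))
        w[rare_idx] = f
        w[np.arange(len(clusters)) != rare_idx] = (1.0 - f) * other
        expected = (mean_mat @ w) * bio[:, s]
        p = expected / expected.sum()
        values[:, s] = rng.multinomial(config.bulk_depth, p)

    lengths = rng.integers(200, 10_001, size=len(profiles)).astype(float)
    bulk = BulkMatrix(
        genes=list(profiles.index),
        samples=samples,
        values=values,
        value_kind="raw_counts",
        gene_lengths=lengths,
    )
    truth = pd.Series(fractions, index=pd.Index(samples, name="sample"), name="rare_fraction")
    return bulk, truth


def simulate_ihc(
    truth: pd.Series,
    config: SimConfig = SimConfig(),
) -> SampleMeta:
    """Noisy reference cell counts (and group labels) from true fractions.

    ``cell_count = round(truth * area_scale * lognormal noise)`` where the
    lognormal has unit mean and coefficient of variation ``ihc_noise_cv``.
    A two-group label is attached; treated samples have their truth
    multiplied by ``group_shift`` before counting (shift < 1 emulates a
    treatment that lowers the rare-cell burden; shift 1 is a null).
    """
    rng = _rng(config, _STREAM_IHC)
    n = len(truth)
    n_treated = int(round(config.treated_fraction * n))
    treated = np.zeros(n, dtype=bool)
    treated[rng.choice(n, size=n_treated, replace=False)] = True
    group = np.where(treated, config.group_labels[0], config.group_labels[1])

    shifted = truth.to_numpy(dtype=float) * np.where(treated, config.group_shift, 1.0)
    if config.ihc_noise_cv > 0:
        sigma2 = math.log1p(config.ihc_noise_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)
    else:
        noise = np.ones(n)
    counts = np.round(shifted * config.ihc_area_scale * noise)
    table = pd.DataFrame(
        {"cell_count": counts, "group": group},
        index=pd.Index(truth.index, name="sample"),
    )
    return SampleMeta(table=table)
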