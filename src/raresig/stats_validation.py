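"""Validation statistics: Pearson correlation with reference cell counts,
Benjamini-Hochberg FDR over a family of signatures, and the Mann-Whitney
rank-sum comparison between sample groups.

These are implemented directly (rather than delegated) because the module
contract pins down their exact behaviour: the exact-enumeration switch for
small tie-free Mann-Whitney problems, midranks with a tie-corrected normal
approximation otherwise, and the BH step-up returned in input order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bulk_scoring import ScoreTable
from .io_formats import SampleMeta

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationResult",
    "GroupStats",
    "GroupComparison",
    "pearson_validation",
    "bh_fdr",
    "mann_whitney",
    "validate_signatures",
    "compare_groups",
]


@dataclass(frozen=True)
class ValidationResult:
    """Pearson validation of one score table against reference counts."""

    n: int
    pearson_r: float
    p_value: float
    q_value: Optional[float] = None
    n_dropped: int = 0  # samples without a reference count


@dataclass(frozen=True)
class GroupStats:
    n: int
    median: float
    sd: float
    mad: float


@dataclass(frozen=True)
class GroupComparison:
    group_a: GroupStats
    group_b: GroupStats
    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal"


def _as_score_series(scores: Union[ScoreTable, pd.Series, Mapping[str, float]]) -> pd.Series:
    if isinstance(scores, ScoreTable):
        return scores.scores
    if isinstance(scores, pd.Series):
        return scores
    return pd.Series(dict(scores), dtype=float)


def pearson_validation(
    scores: Union[ScoreTable, pd.Series, Mapping[str, float]],
    meta: SampleMeta,
) -> ValidationResult:
    """Product-moment correlation between scores and reference cell counts.

    Samples lacking a reference count are dropped (and counted in
    ``n_dropped``); the two-sided p-value comes from the t distribution
    with n - 2 degrees of freedom.
    """
    s = _as_score_series(scores)
    counts = meta.table["cell_count"].reindex(s.index)
    keep = counts.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d sample(s) without a reference cell count", n_dropped)
    x = s[keep].to_numpy(dtype=float)
    y = counts[keep].to_numpy(dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete score/count pairs, got {n}")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = math.sqrt(float(xd @ xd))
    sy = math.sqrt(float(yd @ yd))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in scores or cell counts")
    r = float(xd @ yd) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return ValidationResult(n=n, pearson_r=r, p_value=p, n_dropped=n_dropped)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _group_stats(x: np.ndarray) -> GroupStats:
    return GroupStats(
        n=int(x.size),
        median=float(np.median(x)),
        sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        mad=float(np.median(np.abs(x - np.median(x)))),
    )


def _exact_two_sided_p(ranks: np.ndarray, n1: int, u1: float) -> float:
    """Two-sided exact p by enumerating all rank assignments (no ties)."""
    n = ranks.size
    n2 = n - n1
    mu = n1 * n2 / 2.0
    obs_dev = abs(u1 - mu)
    offset = n1 * (n1 + 1) / 2.0
    hits = 0
    total = 0
    for combo in combinations(range(n), n1):
        u = ranks[list(combo)].sum() - offset
        total += 1
        # tolerance only guards float rank sums; ranks are integers here
        if abs(u - mu) >= obs_dev - 1e-12:
            hits += 1
    return hits / total


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    mode: str = "auto",
) -> GroupComparison:
    """Two-sided Mann-Whitney U test with per-group descriptive statistics.

    ``auto`` uses exact enumeration when n1 + n2 <= 12 and the pooled values
    are tie-free, and otherwise a normal approximation with midranks,
    tie-corrected variance and a 0.5 continuity correction.  ``exact`` with
    ties falls back to the normal approximation with a warning.  The
    reported U is min(U1, U2).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    n1, n2 = a.size, b.size
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    want_exact = mode == "exact" or (mode == "auto" and n <= 12)
    if want_exact and has_ties:
        if mode == "exact":
            logger.warning(
                "ties present; exact Mann-Whitney refuses ties, "
                "falling back to the normal approximation"
            )
        want_exact = False

    if want_exact:
        p = _exact_two_sided_p(ranks, n1, u1)
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        tie_term = float(((tie_counts**3) - tie_counts).sum())
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var == 0:  # all pooled values identical
            p = 1.0
        else:
            z = max(0.0, abs(u1 - mu) - 0.5) / math.sqrt(var)
            p = min(1.0, 2.0 * float(sps.norm.sf(z)))
        method = "normal"
    return GroupComparison(
        group_a=_group_stats(a),
        group_b=_group_stats(b),
        u_statistic=float(u),
        p_value=float(p),
        method=method,
    )


def validate_signatures(
    score_tables: Mapping[str, Union[ScoreTable, pd.Series]],
    meta: SampleMeta,
) -> dict[str, ValidationResult]:
    """Pearson-validate a family of signatures with BH-FDR across the family.

    The FDR family is exactly the set of score tables passed in one call
    (e.g. the 70/75/80% threshold sweep); its size is logged.
    """
    names = list(score_tables)
    if not names:
        raise ValueError("no score tables to validate")
    raw = {name: pearson_validation(score_tables[name], meta) for name in names}
    logger.info("BH-FDR family size: %d signature(s)", len(names))
    q = bh_fdr([raw[name].p_value for name in names])
    return {
        name: ValidationResult(
            n=raw[name].n,
            pearson_r=raw[name].pearson_r,
            p_value=raw[name].p_value,
            q_value=float(q[i]),
            n_dropped=raw[name].n_dropped,
        )
        for i, name in enumerate(names)
    }


def compare_groups(
    scores: Union[ScoreTable, pd.Series, Mapping[str, float]],
    meta: SampleMeta,
    mode: str = "auto",
) -> tuple[tuple[str, str], GroupComparison]:
    """Mann-Whitney comparison of scores between the two metadata groups.

    Returns the (group_a_label, group_b_label) pair, ordered alphabetically,
    alongside the comparison.  Errors unless exactly two groups are present
    among samples that have both a score and a group label.
    """
    s = _as_score_series(scores)
    groups = meta.table["group"].reindex(s.index)
    keep = groups.notna()
    labels = sorted(groups[keep].unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, found {labels}")
    a = s[keep][groups[keep] == labels[0]].to_numpy(dtype=float)
    b = s[keep][groups[keep] == labels[1]].to_numpy(dtype=float)
    return (labels[0], labels[1]), mann_whitney(a, b, mode=mode)
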