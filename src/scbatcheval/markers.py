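"""Marker-gene detection and cross-batch consistency scoring.

A gene is a marker for a cell population when it passes three gates
against all remaining cells:

* |log fold-change| > 2 (natural log of population vs rest mean of the
  de-logged expression, with pseudocount 1);
* detected (expression > 0) in at least half of the population's cells;
* two-sided Wilcoxon rank-sum adjusted P < 0.05 (Bonferroni by default,
  Benjamini–Hochberg by flag), normal approximation with tie correction.

Consistency between the merged (possibly batch-corrected) dataset and the
individual batches is scored per population with the multiple-site
generalized Jaccard index

    J_N = (Σ_i |A_i| − |∪ A_i|) / ((N − 1) · |∪ A_i|),

which reduces to the classic Jaccard |A∩B| / |A∪B| at N = 2, restricted to
the populations present in every batch.  The fraction of populations for
which the merged data yields any marker at all is reported alongside —
an aggressive correction can erase markers entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .core import ExpressionDataset

__all__ = [
    "MarkerSet",
    "ConsistencyScore",
    "find_markers",
    "generalized_jaccard",
    "compare_markers",
    "rank_sum_test",
]

MIN_GROUP = 3


def rank_sum_test(x, y, method: str = "asymptotic", axis: int = 0):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-values.

    ``asymptotic`` uses the tie-corrected normal approximation (the default
    the marker gates run on); ``exact`` enumerates the null permutation
    distribution and is available for small groups.  Returns (U, p).
    """
    res = mannwhitneyu(x, y, axis=axis, alternative="two-sided", method=method)
    return np.asarray(res.statistic), np.asarray(res.pvalue)


@dataclass
class MarkerSet:
    population: str
    genes: set[str]
    stats: pd.DataFrame  # per gene: log_fc, pct_in, pct_out, p_value, p_adjusted
    source: str = "merged"
    reason: str | None = None  # set when empty for a structural reason


@dataclass
class ConsistencyScore:
    per_population: dict[str, float | None]  # None = undefined (no markers anywhere)
    fraction_with_markers: float
    populations_compared: list[str] = field(default_factory=list)


def find_markers(dataset: ExpressionDataset, population: str, *,
                 layer: str | None = None, min_abs_logfc: float = 2.0,
                 min_detection: float = 0.5, alpha: float = 0.05,
                 adjust: str = "bonferroni", detection_both_groups: bool = False,
                 pseudocount: float = 1.0, source: str = "merged") -> MarkerSet:
    """Markers of one population versus all other cells.

    The log layer is de-logged with expm1 before computing fold-changes so
    the ratio is on the expression scale.  Populations (or rests) smaller
    than 3 cells return an empty set with a reason rather than raising.
    """
    type_labels = np.asarray(dataset.cell_type, dtype=object).astype(str)
    if population not in set(type_labels):
        raise ValueError(f"population {population!r} not present in dataset")
    in_mask = type_labels == population
    empty = MarkerSet(population=population, genes=set(),
                      stats=pd.DataFrame(), source=source)
    if in_mask.sum() < MIN_GROUP or (~in_mask).sum() < MIN_GROUP:
        empty.reason = "population or rest below minimum group size"
        return empty

    X = np.asarray(dataset.X(layer), dtype=float)
    x_in, x_out = X[in_mask], X[~in_mask]

    # vectorized tie-corrected normal-approximation rank-sum across genes
    _, p = rank_sum_test(x_in, x_out, method="asymptotic", axis=0)

    mean_in = np.expm1(x_in).mean(axis=0)
    mean_out = np.expm1(x_out).mean(axis=0)
    log_fc = np.log(mean_in + pseudocount) - np.log(mean_out + pseudocount)
    pct_in = (x_in > 0).mean(axis=0)
    pct_out = (x_out > 0).mean(axis=0)

    if adjust == "bonferroni":
        p_adj = np.minimum(p * len(p), 1.0)
    elif adjust in ("bh", "fdr_bh"):
        p_adj = multipletests(p, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    detected = pct_in >= min_detection
    if detection_both_groups:
        detected &= pct_out >= min_detection
    is_marker = (np.abs(log_fc) > min_abs_logfc) & detected & (p_adj < alpha)

    stats = pd.DataFrame(
        {
            "gene": np.asarray(dataset.gene_ids, dtype=object).astype(str),
            "log_fc": log_fc,
            "pct_in": pct_in,
            "pct_out": pct_out,
            "p_value": p,
            "p_adjusted": p_adj,
            "is_marker": is_marker,
        }
    )
    genes = set(stats.loc[stats["is_marker"], "gene"])
    return MarkerSet(population=population, genes=genes, stats=stats, source=source)


def generalized_jaccard(sets) -> float | None:
    """Multiple-site generalized Jaccard of N ≥ 2 sets, in [0, 1].

    J_N = (Σ|A_i| − |∪A_i|) / ((N−1)·|∪A_i|); equals 1 for identical
    non-empty sets, 0 for pairwise-disjoint sets, and classic Jaccard at
    N = 2.  All-empty input is undefined and returns None (reported as
    missing, never as 0).
    """
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("generalized Jaccard needs at least 2 sets")
    union = set().union(*sets)
    if not union:
        return None
    total = sum(len(s) for s in sets)
    return (total - len(union)) / ((len(sets) - 1) * len(union))


def compare_markers(merged: ExpressionDataset, batches, **marker_kwargs) -> ConsistencyScore:
    """Marker consistency between a merged dataset and its batches.

    Restricted to populations present in every individual batch.  For each
    such population the generalized Jaccard is taken over the merged
    marker set together with one set per batch; populations with no marker
    in any of those sets score None (missing).  Also reports the fraction
    of compared populations for which the merged data yields ≥ 1 marker.
    """
    batches = list(batches)
    if not batches:
        raise ValueError("at least one batch dataset required")
    for b in batches:
        if not np.array_equal(b.gene_ids, merged.gene_ids):
            raise ValueError("merged and batch datasets must share the gene space")

    def populations(ds):
        return set(np.asarray(ds.cell_type, dtype=object).astype(str))

    common = populations(batches[0])
    for b in batches[1:]:
        common &= populations(b)
    common &= populations(merged)
    if not common:
        raise ValueError("no cell populations are common to all batches")
    common = sorted(common)

    per_population: dict[str, float | None] = {}
    merged_has_markers = 0
    for pop in common:
        merged_set = find_markers(merged, pop, source="merged", **marker_kwargs)
        batch_sets = [
            find_markers(b, pop, source=f"batch{i}", **marker_kwargs)
            for i, b in enumerate(batches)
        ]
        if merged_set.genes:
            merged_has_markers += 1
        per_population[pop] = generalized_jaccard(
            [merged_set.genes] + [s.genes for s in batch_sets]
        )
    return ConsistencyScore(
        per_population=per_population,
        fraction_with_markers=merged_has_markers / len(common),
        populations_compared=common,
    )
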