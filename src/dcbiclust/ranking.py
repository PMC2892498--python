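"""Meta-ranking: merge bicluster lists from several algorithms into one ranking.

Different biclustering algorithms optimise incomparable objectives, so their
native ranks cannot be compared directly.  Scoring every bicluster with the
same differential co-expression goodness score SB puts them on one scale;
sorting by SB yields a unified ("meta") ranking from which per-algorithm
rank distributions, top-n composition profiles and type compositions are
summarised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import NotScorableError
from .matrix import Bicluster, ExpressionMatrix
from .scoring import DEFAULT_FUDGE, DEFAULT_PHI, BiclusterAssessment, assess_bicluster

logger = logging.getLogger(__name__)

__all__ = [
    "BiclusterCollection",
    "RankedAssessments",
    "filter_small_biclusters",
    "unified_ranking",
    "rank_distribution",
    "top_n_composition",
    "summarize_collection",
    "type_composition",
    "overlap_report",
]

DEFAULT_MIN_CONDITIONS = 5


@dataclass
class BiclusterCollection:
    """Biclusters pooled from one or more algorithms on one dataset.

    Loading assigns each bicluster a unique id (explicit id, else
    ``source_algorithm:source_rank``, else a positional fallback).
    """

    biclusters: list[Bicluster]
    dataset_label: str = ""

    def __post_init__(self):
        seen: dict[str, int] = {}
        fixed = []
        for pos, b in enumerate(self.biclusters):
            bid = b.id if b.id is not None else (
                f"{b.source_algorithm}:{b.source_rank}"
                if b.source_rank is not None
                else f"{b.source_algorithm}:#{pos}"
            )
            if bid in seen:
                seen[bid] += 1
                bid = f"{bid}.{seen[bid]}"
            else:
                seen[bid] = 0
            fixed.append(Bicluster(b.gene_ids, b.condition_ids, b.source_algorithm, b.source_rank, bid))
        self.biclusters = fixed

    def __len__(self) -> int:
        return len(self.biclusters)

    def sources(self) -> list[str]:
        return sorted({b.source_algorithm for b in self.biclusters})


@dataclass
class RankedAssessments:
    """Assessments ordered by SB descending with contiguous 1-based unified ranks."""

    entries: list[BiclusterAssessment]
    unified_ranks: list[int] = field(init=False)
    not_scorable: list[tuple[Bicluster, str]] = field(default_factory=list)

    def __post_init__(self):
        self.unified_ranks = list(range(1, len(self.entries) + 1))

    def __len__(self) -> int:
        return len(self.entries)


def filter_small_biclusters(
    collection: BiclusterCollection, min_conditions: int = DEFAULT_MIN_CONDITIONS
) -> BiclusterCollection:
    """Drop biclusters spanning fewer than ``min_conditions`` conditions.

    Small-condition biclusters look artificially strong simply because few
    columns are easy to fit, hence the default threshold of 5.
    """
    if min_conditions < 1:
        raise ValueError(f"min_conditions must be >= 1, got {min_conditions}")
    kept = [b for b in collection.biclusters if b.n_conditions >= min_conditions]
    removed = len(collection.biclusters) - len(kept)
    if removed:
        logger.info(
            "filtered %d bicluster(s) with fewer than %d conditions", removed, min_conditions
        )
    return BiclusterCollection(kept, collection.dataset_label)


def unified_ranking(
    matrix: ExpressionMatrix,
    collection: BiclusterCollection,
    a: float = DEFAULT_FUDGE,
    phi: float = DEFAULT_PHI,
) -> RankedAssessments:
    """Assess every bicluster and sort by SB descending.

    Ties break on larger gene count, then lexicographic bicluster id, so the
    ranking is deterministic.  Not-scorable biclusters (degenerate groups)
    are excluded from the ranking and reported on ``not_scorable``.
    """
    assessed: list[BiclusterAssessment] = []
    dropped: list[tuple[Bicluster, str]] = []
    for b in collection.biclusters:
        try:
            assessed.append(assess_bicluster(matrix, b, a=a, phi=phi))
        except NotScorableError as exc:
            dropped.append((b, str(exc)))
    if dropped:
        logger.info("excluded %d not-scorable bicluster(s) from the ranking", len(dropped))
    assessed.sort(key=lambda asmt: (-asmt.SB, -asmt.bicluster.n_genes, asmt.bicluster.label))
    ranked = RankedAssessments(assessed)
    ranked.not_scorable = dropped
    return ranked


def _median(values: list[float]) -> float:
    # mean-of-middle convention for even counts
    return float(np.median(values))


def rank_distribution(ranked: RankedAssessments) -> dict[str, dict]:
    """Per-source unified ranks with summary quantiles (min, quartiles, median, max)."""
    per_source: dict[str, list[int]] = {}
    for rank, asmt in zip(ranked.unified_ranks, ranked.entries):
        per_source.setdefault(asmt.bicluster.source_algorithm, []).append(rank)
    out: dict[str, dict] = {}
    for source in sorted(per_source):
        ranks = per_source[source]
        q = np.percentile(ranks, [0, 25, 50, 75, 100])
        out[source] = {
            "ranks": ranks,
            "min": float(q[0]),
            "q1": float(q[1]),
            "median": float(q[2]),
            "q3": float(q[3]),
            "max": float(q[4]),
        }
    return out


def top_n_composition(ranked: RankedAssessments, n: int = 100) -> dict:
    """Percent contribution of each source at every prefix 1..min(n, total).

    Percentages sum to 100 at every prefix length.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    total = len(ranked.entries)
    if n > total:
        logger.info("top-n composition truncated to list length %d (requested %d)", total, n)
    limit = min(n, total)
    sources = sorted({a.bicluster.source_algorithm for a in ranked.entries[:limit]})
    counts = {s: 0 for s in sources}
    profile: dict[str, list[float]] = {s: [] for s in sources}
    for k in range(limit):
        counts[ranked.entries[k].bicluster.source_algorithm] += 1
        for s in sources:
            profile[s].append(100.0 * counts[s] / (k + 1))
    return {"prefix_lengths": list(range(1, limit + 1)), "percent": profile}


def summarize_collection(collection: BiclusterCollection) -> dict[str, dict]:
    """Per-source bicluster count and median gene/condition sizes."""
    per_source: dict[str, list[Bicluster]] = {}
    for b in collection.biclusters:
        per_source.setdefault(b.source_algorithm, []).append(b)
    return {
        source: {
            "count": len(bs),
            "median_conditions": _median([b.n_conditions for b in bs]),
            "median_genes": _median([b.n_genes for b in bs]),
        }
        for source, bs in sorted(per_source.items())
    }


def type_composition(ranked: RankedAssessments) -> dict[str, dict]:
    """Per-source counts of T/B/mu types and the sorted TS values.

    The sorted TS values per source give the cumulative stratification
    distribution directly.
    """
    per_source: dict[str, list[BiclusterAssessment]] = {}
    for asmt in ranked.entries:
        per_source.setdefault(asmt.bicluster.source_algorithm, []).append(asmt)
    out: dict[str, dict] = {}
    for source, asmts in sorted(per_source.items()):
        types = {"T": 0, "B": 0, "mu": 0, "unclassified": 0}
        for asmt in asmts:
            types[asmt.coexpression_type] += 1
        out[source] = {"types": types, "TS_sorted": sorted(a.TS for a in asmts)}
    return out


def _jaccard(x: frozenset, y: frozenset) -> float:
    union = len(x | y)
    return len(x & y) / union if union else 0.0


def overlap_report(collection: BiclusterCollection, min_jaccard: float = 0.5) -> list[dict]:
    """Optional diagnostic: pairs of biclusters overlapping heavily.

    Duplicates across algorithms are never removed from the ranking; this
    report just surfaces them.  Returns pairs whose gene-set and
    condition-set Jaccard indices both reach ``min_jaccard``.
    """
    pairs = []
    bs = collection.biclusters
    for i in range(len(bs)):
        for j in range(i + 1, len(bs)):
            jg = _jaccard(bs[i].gene_ids, bs[j].gene_ids)
            jc = _jaccard(bs[i].condition_ids, bs[j].condition_ids)
            if jg >= min_jaccard and jc >= min_jaccard:
                pairs.append(
                    {
                        "id_a": bs[i].label,
                        "id_b": bs[j].label,
                        "gene_jaccard": jg,
                        "condition_jaccard": jc,
                    }
                )
    return pairs
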