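"""Ranking-evaluation statistics: top-k intersection benchmarks and the
weighted Kolmogorov-Smirnov running-sum enrichment score with permutation
p-values."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentScoreResult",
    "validate_ranking",
    "benchmark_intersection",
    "ks_running_sum",
    "permutation_pvalue",
]

DEFAULT_TOP_K = 100
DEFAULT_N_PERM = 1000


@dataclass
class EnrichmentScoreResult:
    es: float
    p_value: float
    n_permutations: int


def validate_ranking(ranking: Sequence[str]) -> list[str]:
    items = list(ranking)
    if len(set(items)) != len(items):
        raise ValueError("ranking contains duplicate ids")
    return items


def benchmark_intersection(
    rankings: Sequence[Sequence[str]], top_k: int = DEFAULT_TOP_K
) -> set[str]:
    """Intersection of the ``top_k`` prefixes of two or more rankings.

    Rankings shorter than ``top_k`` contribute their full list (warned)."""
    if len(rankings) < 2:
        raise ValueError("need at least 2 rankings to intersect")
    prefixes = []
    for ranking in rankings:
        items = validate_ranking(ranking)
        if len(items) < top_k:
            log.warning(
                "ranking has only %d items (< top_k=%d); using full list",
                len(items), top_k,
            )
        prefixes.append(set(items[:top_k]))
    out = prefixes[0]
    for pref in prefixes[1:]:
        out = out & pref
    return out


def _es_from_hits(hits: np.ndarray, two_sided: bool = False) -> float:
    """Running-sum enrichment score from a boolean hit indicator array.

    Hits contribute +sqrt((m-h)/h), misses -sqrt(h/(m-h)); the score is the
    maximum prefix sum (the empty prefix, 0, included), or the maximum
    absolute deviation in two-sided mode.  The full sum is always 0."""
    m = hits.size
    h = int(hits.sum())
    if h == 0 or h == m:
        raise ValueError("benchmark must be a strict non-empty subset of the ranking")
    up = math.sqrt((m - h) / h)
    down = math.sqrt(h / (m - h))
    steps = np.where(hits, up, -down)
    running = np.cumsum(steps)
    if two_sided:
        return float(np.max(np.abs(running)))
    return float(max(0.0, np.max(running)))


def ks_running_sum(
    ranking: Sequence[str], benchmark: set[str], two_sided: bool = False
) -> float:
    """Enrichment score of the benchmark ids within the ranking (best first)."""
    items = validate_ranking(ranking)
    if not benchmark:
        raise ValueError("benchmark set is empty")
    missing = benchmark - set(items)
    if missing:
        raise ValueError(f"benchmark ids absent from the ranking: {sorted(missing)[:5]}")
    hits = np.array([item in benchmark for item in items])
    return _es_from_hits(hits, two_sided=two_sided)


def permutation_pvalue(
    ranking: Sequence[str],
    benchmark: set[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    two_sided: bool = False,
) -> EnrichmentScoreResult:
    """Permutation p-value of the enrichment score.

    p = (1 + #{permuted es >= observed}) / (n_perm + 1): the add-one form
    never returns 0, so the floor is 1/(n_perm+1) (0.001 at the default 1000
    permutations).  Permutations shuffle the ranking with a seeded generator
    and are reproducible given the seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    items = validate_ranking(ranking)
    observed = ks_running_sum(items, benchmark, two_sided=two_sided)
    hits = np.array([item in benchmark for item in items])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(hits)
        if _es_from_hits(perm, two_sided=two_sided) >= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return EnrichmentScoreResult(es=observed, p_value=p, n_permutations=n_perm)
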