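"""Over-representation baseline: one-sided Fisher's exact test and BH FDR."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.stats

from .io import GeneSetCollection, Network, ValidationError

__all__ = [
    "OverlapTable",
    "overlap_table",
    "fisher_overrep",
    "bh_adjust",
    "universe",
]


@dataclass(frozen=True)
class OverlapTable:
    """2x2 membership counts: overlap k, target size t, reference size m,
    universe size N (all restricted to the universe)."""

    k: int
    t: int
    m: int
    N: int

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValidationError("universe must be non-empty")
        if not (0 <= self.t <= self.N and 0 <= self.m <= self.N):
            raise ValidationError(f"set sizes out of range: {self}")
        if not (0 <= self.k <= min(self.t, self.m)):
            raise ValidationError(f"overlap out of range: {self}")


def overlap_table(
    target: Iterable[str], reference: Iterable[str], universe_set: set[str]
) -> OverlapTable:
    """Build the contingency table, restricting both sets to the universe."""
    t_in = set(target) & universe_set
    m_in = set(reference) & universe_set
    return OverlapTable(
        k=len(t_in & m_in), t=len(t_in), m=len(m_in), N=len(universe_set)
    )


def fisher_overrep(tab: OverlapTable) -> float:
    """One-sided Fisher's exact p-value P(X >= k), X ~ Hypergeom(N, m, t)."""
    # sf(k-1) is the exact upper tail; k=0 gives exactly 1.0
    return float(scipy.stats.hypergeom.sf(tab.k - 1, tab.N, tab.m, tab.t))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    # guard against 1-ulp rounding in p*m/rank: q >= p holds exactly in theory
    q_sorted = np.maximum(q_sorted, p[order])
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def universe(
    net: Network, refs: GeneSetCollection, mode: str = "network_nodes"
) -> set[str]:
    """Gene universe for the contingency tables.

    ``network_nodes`` (default) uses all network node ids, so the ORA and the
    network score see the same gene space; ``union_of_refs`` uses the union
    of the reference set members."""
    if mode == "network_nodes":
        uni = net.nodes
    elif mode == "union_of_refs":
        uni = set()
        for gs in refs:
            uni |= gs.members
    else:
        raise ValueError(f"unknown universe mode {mode!r}")
    if not uni:
        raise ValidationError("empty gene universe")
    return uni
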