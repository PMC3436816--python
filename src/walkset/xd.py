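"""The Xd distance-bin association statistic.

Distance scores of every reference set's mapped nodes are pooled into a
background, discretized into ``n`` bins, and each reference set's own
distance profile is compared against the background by

    Xd = sum_i (P_ic - P_ia) / i,        i = 1..n

where ``P_ic`` is the fraction of the set's distance scores in bin ``i`` and
``P_ia`` the background fraction.  Division by the bin number down-weights
far bins, so concentration of a set near the seed genes raises the score.

Binning defaults to equal-frequency quantiles of the pooled distances
(making the background near-uniform); equal-width binning over the observed
range is available via ``mode="width"`` and is also the automatic fallback
when the pooled values carry too few distinct values for quantile cuts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .io import MappedSet, Network, TissueAnnotation
from .rwr import (
    DEFAULT_MAX_ITER,
    DEFAULT_RESTART_PROB,
    DEFAULT_TOL,
    DistanceVector,
    random_walk_with_restart,
    to_distances,
)

log = logging.getLogger(__name__)

__all__ = [
    "BinScheme",
    "PathwayProfile",
    "XdResult",
    "build_bin_scheme",
    "profile_scores",
    "profile_pathway",
    "xd_score",
    "score_collection",
    "compare_tissue_groups",
]

DEFAULT_N_BINS = 10


@dataclass
class BinScheme:
    """Distance bins plus the pooled all-set background fractions ``P_ia``."""

    n_bins: int
    edges: np.ndarray  # n_bins + 1 strictly increasing cut points
    background_fractions: np.ndarray  # sums to 1
    mode: str = "quantile"
    fallback_used: bool = False

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin index per value; bins are left-closed/right-open, last bin
        right-closed; values outside the edge range clamp to the end bins."""
        idx = np.searchsorted(self.edges, values, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


@dataclass
class PathwayProfile:
    """Binned fraction profile ``P_ic`` of one reference set's distances."""

    set_id: str
    fractions: np.ndarray
    n_scores: int

    @property
    def empty(self) -> bool:
        return self.n_scores == 0


@dataclass
class XdResult:
    set_id: str
    xd: float  # NaN when the set is not scorable
    n_scores: int
    overlap: int
    tissue_scores: dict[str, float] | None = None


def build_bin_scheme(
    pooled: np.ndarray, n_bins: int = DEFAULT_N_BINS, mode: str = "quantile"
) -> BinScheme:
    """Build bin edges and background fractions from the pooled distances.

    Quantile mode places edges at equal-frequency quantiles so that the
    background is near-uniform (P_ia ~ 1/n up to ties).  If the pooled values
    have fewer distinct values than bins, or the quantile cuts collide,
    equal-width edges over the observed range are used instead (logged).
    """
    pooled = np.asarray(pooled, dtype=float)
    if pooled.size == 0:
        raise ValueError("cannot build a bin scheme from an empty pool")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if mode not in ("quantile", "width"):
        raise ValueError(f"unknown binning mode {mode!r}")

    fallback = False
    edges: np.ndarray | None = None
    if mode == "quantile":
        if np.unique(pooled).size >= n_bins:
            q = np.quantile(pooled, np.linspace(0.0, 1.0, n_bins + 1))
            if np.unique(q).size == n_bins + 1:
                edges = q
        if edges is None:
            fallback = True
            log.warning(
                "too few distinct pooled values for %d quantile bins; "
                "falling back to equal-width bins",
                n_bins,
            )
    if edges is None:
        lo, hi = float(pooled.min()), float(pooled.max())
        if lo == hi:  # degenerate: widen artificially so edges stay increasing
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, n_bins + 1)

    scheme = BinScheme(
        n_bins=n_bins,
        edges=edges,
        background_fractions=np.zeros(n_bins),
        mode=mode,
        fallback_used=fallback,
    )
    counts = np.bincount(scheme.assign(pooled), minlength=n_bins)
    scheme.background_fractions = counts / pooled.size
    return scheme


def profile_scores(values: np.ndarray, scheme: BinScheme, set_id: str = "") -> PathwayProfile:
    """Bin raw distance values into a normalized fraction profile."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return PathwayProfile(set_id=set_id, fractions=np.zeros(scheme.n_bins), n_scores=0)
    counts = np.bincount(scheme.assign(values), minlength=scheme.n_bins)
    return PathwayProfile(
        set_id=set_id, fractions=counts / values.size, n_scores=int(values.size)
    )


def profile_pathway(
    dv: DistanceVector,
    ref: MappedSet,
    scheme: BinScheme,
    tissue_filter: set[str] | None = None,
) -> PathwayProfile:
    """Profile a mapped reference set's distances, optionally restricted to
    the nodes in ``tissue_filter``.  An empty selection yields an empty
    profile (Xd undefined downstream), never a zero score."""
    nodes = ref.mapped if tissue_filter is None else ref.mapped & tissue_filter
    values = np.array([dv[v] for v in sorted(nodes)])
    return profile_scores(values, scheme, set_id=ref.set_id)


def xd_score(
    profile: PathwayProfile, scheme: BinScheme, divide_by_n: bool = False
) -> float:
    """Compute Xd = sum_i (P_ic - P_ia)/i over the bins (fractions in [0,1]).

    Returns NaN for an empty profile.  ``divide_by_n`` additionally divides
    by the bin count (alternative normalization, off by default)."""
    if profile.empty:
        return math.nan
    i = np.arange(1, scheme.n_bins + 1)
    xd = float(np.sum((profile.fractions - scheme.background_fractions) / i))
    if divide_by_n:
        xd /= scheme.n_bins
    return xd


def _pool_distances(dv: DistanceVector, refs: list[MappedSet],
                    tissue_filter: set[str] | None = None) -> np.ndarray:
    vals: list[float] = []
    for ref in refs:
        nodes = ref.mapped if tissue_filter is None else ref.mapped & tissue_filter
        vals.extend(dv[v] for v in sorted(nodes))
    return np.array(vals)


def score_collection(
    net: Network,
    target: MappedSet,
    refs: list[MappedSet],
    r: float = DEFAULT_RESTART_PROB,
    n_bins: int = DEFAULT_N_BINS,
    tissue: TissueAnnotation | None = None,
    binning: str = "quantile",
    divide_by_n: bool = False,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> list[XdResult]:
    """Score every reference set against the target set.

    Runs one RWR from the target seeds, pools the distances of all scorable
    reference sets into one background, and computes one Xd per set.  When
    tissue annotations are given, a per-tissue score is added for every
    tissue label, restricting both the set profile and the pooled background
    to that tissue's nodes (matched background).  Results are sorted by Xd
    descending; unscorable sets (NaN) sort last.
    """
    if not target.scorable:
        raise ValueError("target set has no members mapped to the network")
    scorable = [ref for ref in refs if ref.scorable]
    if not scorable:
        raise ValueError("no reference set maps to the network")

    rv = random_walk_with_restart(net, target.mapped, r=r, tol=tol, max_iter=max_iter)
    dv = to_distances(rv)

    pooled = _pool_distances(dv, scorable)
    scheme = build_bin_scheme(pooled, n_bins=n_bins, mode=binning)

    tissue_schemes: dict[str, tuple[set[str], BinScheme | None]] = {}
    if tissue is not None:
        for label in tissue.tissues():
            filt = tissue.genes_for(label)
            pooled_t = _pool_distances(dv, scorable, tissue_filter=filt)
            scheme_t = (
                build_bin_scheme(pooled_t, n_bins=n_bins, mode=binning)
                if pooled_t.size
                else None
            )
            tissue_schemes[label] = (filt, scheme_t)

    results: list[XdResult] = []
    for ref in refs:
        if not ref.scorable:
            results.append(
                XdResult(set_id=ref.set_id, xd=math.nan, n_scores=0,
                         overlap=len(target.mapped & ref.mapped))
            )
            continue
        prof = profile_pathway(dv, ref, scheme)
        xd = xd_score(prof, scheme, divide_by_n=divide_by_n)
        tissue_scores: dict[str, float] | None = None
        if tissue is not None:
            tissue_scores = {}
            for label, (filt, scheme_t) in tissue_schemes.items():
                if scheme_t is None:
                    tissue_scores[label] = math.nan
                    continue
                prof_t = profile_pathway(dv, ref, scheme_t, tissue_filter=filt)
                tissue_scores[label] = xd_score(prof_t, scheme_t, divide_by_n=divide_by_n)
        results.append(
            XdResult(
                set_id=ref.set_id,
                xd=xd,
                n_scores=prof.n_scores,
                overlap=len(target.mapped & ref.mapped),
                tissue_scores=tissue_scores,
            )
        )

    results.sort(key=lambda res: (math.isnan(res.xd), -res.xd if not math.isnan(res.xd) else 0.0, res.set_id))
    return results


def compare_tissue_groups(
    tissue_scores: dict[str, float],
    group_a: set[str],
    group_b: set[str],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U comparison of per-tissue Xd scores between two tissue
    groups (convenience utility; e.g. brain vs non-brain).  NaN scores are
    dropped.  Returns ``(U, p_value)``."""
    a = [tissue_scores[t] for t in sorted(group_a)
         if t in tissue_scores and not math.isnan(tissue_scores[t])]
    b = [tissue_scores[t] for t in sorted(group_b)
         if t in tissue_scores and not math.isnan(tissue_scores[t])]
    if not a or not b:
        raise ValueError("both tissue groups need at least one finite score")
    stat = scipy.stats.mannwhitneyu(a, b, alternative=alternative)
    return float(stat.statistic), float(stat.pvalue)
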