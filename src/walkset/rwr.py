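"""Random walk with restart on a weighted network.

The walk iterates ``p <- (1 - r) * T p + r * p0`` where ``T`` is the
column-stochastic transition operator (transition probabilities proportional
to edge weights), ``r`` the restart probability and ``p0`` the uniform
distribution over the seed nodes.  Mass sitting on dangling (isolated) nodes
is redirected to ``p0`` every iteration so total probability is conserved.

The fixed point is deterministic; no randomness is involved anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import Network

log = logging.getLogger(__name__)

__all__ = [
    "TransitionOperator",
    "RelevanceVector",
    "DistanceVector",
    "build_transition_operator",
    "random_walk_with_restart",
    "to_distances",
]

DEFAULT_RESTART_PROB = 0.9
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 1000


@dataclass
class TransitionOperator:
    """Column-stochastic transition matrix over a fixed node ordering.

    ``matrix[i, j]`` is the probability of stepping from node ``j`` to node
    ``i``.  Columns of dangling nodes (no incident edges) are zero and flagged
    in ``dangling``; their outgoing mass is returned to the restart
    distribution by the walk.
    """

    nodes: list[str]
    index: dict[str, int]
    matrix: sp.csr_matrix
    dangling: np.ndarray  # bool per node


@dataclass
class RelevanceVector:
    """Steady-state probability of the walk per node."""

    scores: dict[str, float]
    restart_prob: float
    iterations_used: int
    converged: bool

    def as_array(self, nodes: list[str]) -> np.ndarray:
        return np.array([self.scores[n] for n in nodes])


@dataclass
class DistanceVector:
    """Per-node distance scores: 1 minus the steady-state relevance."""

    distances: dict[str, float]

    def __getitem__(self, node: str) -> float:
        return self.distances[node]


def build_transition_operator(net: Network) -> TransitionOperator:
    """Build the weight-proportional column-stochastic transition operator."""
    if net.n_nodes == 0:
        raise ValueError("cannot build a transition operator for an empty network")
    nodes = sorted(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for u, v, w in net.edges():
        iu, iv = index[u], index[v]
        rows.append(iu); cols.append(iv); vals.append(w)
        rows.append(iv); cols.append(iu); vals.append(w)
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    colsum = np.asarray(mat.sum(axis=0)).ravel()
    dangling = colsum == 0.0
    scale = np.where(dangling, 1.0, colsum)
    mat = mat @ sp.diags(1.0 / scale)
    return TransitionOperator(
        nodes=nodes, index=index, matrix=mat.tocsr(), dangling=dangling
    )


def random_walk_with_restart(
    net: Network,
    seeds: set[str],
    r: float = DEFAULT_RESTART_PROB,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RelevanceVector:
    """Iterate the walk to its fixed point from a uniform seed distribution.

    Seeds absent from the network are dropped with a logged count; an empty
    effective seed set is an error.  Convergence is declared when the L1
    change between iterations falls below ``tol``.
    """
    if not (0.0 < r < 1.0):
        raise ValueError(f"restart probability must be in (0, 1), got {r}")
    if not seeds:
        raise ValueError("seed set is empty")
    op = build_transition_operator(net)
    present = sorted(set(seeds) & set(op.index))
    n_dropped = len(set(seeds)) - len(present)
    if n_dropped:
        log.info("dropped %d seed(s) not present in the network", n_dropped)
    if not present:
        raise ValueError("no seed maps to the network")

    n = len(op.nodes)
    p0 = np.zeros(n)
    p0[[op.index[s] for s in present]] = 1.0 / len(present)

    p = p0.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        lost = p[op.dangling].sum() if op.dangling.any() else 0.0
        p_next = (1.0 - r) * (op.matrix @ p + lost * p0) + r * p0
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < tol:
            converged = True
            break
    if not converged:
        log.warning("RWR did not converge after %d iterations", max_iter)
    return RelevanceVector(
        scores={node: float(p[i]) for i, node in enumerate(op.nodes)},
        restart_prob=r,
        iterations_used=iterations,
        converged=converged,
    )


def to_distances(rv: RelevanceVector) -> DistanceVector:
    """Convert relevance scores to distance scores by subtraction from 1."""
    return DistanceVector({node: 1.0 - s for node, s in rv.scores.items()})
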