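"""Synthetic benchmark generator: scale-free networks with planted
target-to-pathway wiring, plus matching gene sets and tissue annotations.

The base topology is preferential attachment (interactomes are heavy-tailed);
a configuration-model alternative sits behind ``base_model="config"``.  For
each planted pathway, every (target gene, pathway gene) pair gains an edge
with probability ``p_conn`` and a high-confidence weight in [0.5, 1.0], so a
network-aware statistic should detect the association even when the member
overlap is small or zero.  Everything is deterministic under the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from . import io as wio
from .io import GeneSet, GeneSetCollection, Network, TissueAnnotation

log = logging.getLogger(__name__)

__all__ = ["SyntheticSpec", "SyntheticBundle", "generate", "write_fixture"]

TARGET_SET_ID = "TARGET"


@dataclass
class SyntheticSpec:
    n_nodes: int = 300
    attachment: int = 3  # edges per new node in preferential attachment
    target_size: int = 15
    pathway_sizes: list[int] = field(default_factory=lambda: [30] * 8)
    planted: list[tuple[str, float]] = field(
        default_factory=lambda: [("PW1", 0.3)]
    )
    # membership overlap plan: (pathway_id, n shared genes).  Drawing part of
    # the target from named pathways gives the Fisher q-values enough spread
    # to anchor the threshold regression at small collection sizes.
    target_overlap: list[tuple[str, int]] = field(
        default_factory=lambda: [("PW2", 6), ("PW3", 4), ("PW4", 3), ("PW5", 2)]
    )
    seed: int = 0
    base_model: str = "pa"  # "pa" or "config"
    n_tissues: int = 3
    planted_tissue: str = "tissue_planted"

    def pathway_ids(self) -> list[str]:
        return [f"PW{i + 1}" for i in range(len(self.pathway_sizes))]

    def validate(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes")
        if not (1 <= self.attachment < self.n_nodes):
            raise ValueError("attachment parameter out of range")
        if not (1 <= self.target_size <= self.n_nodes):
            raise ValueError("target size out of range")
        if any(s < 1 for s in self.pathway_sizes):
            raise ValueError("pathway sizes must be >= 1")
        if sum(self.pathway_sizes) > self.n_nodes:
            raise ValueError("pathways (kept disjoint) cannot exceed the node count")
        ids = set(self.pathway_ids())
        for pid, p_conn in self.planted:
            if pid not in ids:
                raise ValueError(f"planted pathway {pid!r} not among {sorted(ids)}")
            if not (0.0 <= p_conn <= 1.0):
                raise ValueError("wiring probability must lie in [0, 1]")
        sizes = dict(zip(self.pathway_ids(), self.pathway_sizes))
        for pid, n_shared in self.target_overlap:
            if pid not in ids:
                raise ValueError(f"overlap pathway {pid!r} not among {sorted(ids)}")
            if not (0 <= n_shared <= sizes[pid]):
                raise ValueError(f"overlap with {pid!r} exceeds its size")
        if sum(n for _, n in self.target_overlap) > self.target_size:
            raise ValueError("overlap plan exceeds the target size")
        if self.base_model not in ("pa", "config"):
            raise ValueError(f"unknown base model {self.base_model!r}")
        if self.n_tissues < 1:
            raise ValueError("need at least one tissue")


@dataclass
class SyntheticBundle:
    network: Network
    target: GeneSet
    pathways: GeneSetCollection
    tissue: TissueAnnotation
    spec: SyntheticSpec


def _base_graph(spec: SyntheticSpec, rng: np.random.Generator) -> nx.Graph:
    gseed = int(rng.integers(2**31 - 1))
    if spec.base_model == "pa":
        return nx.barabasi_albert_graph(spec.n_nodes, spec.attachment, seed=gseed)
    # configuration model with a heavy-tailed degree sequence
    seq = [max(1, int(d)) for d in nx.utils.powerlaw_sequence(spec.n_nodes, 2.5, seed=gseed)]
    if sum(seq) % 2:
        seq[0] += 1
    g = nx.configuration_model(seq, seed=gseed)
    g = nx.Graph(g)  # collapse multi-edges
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def generate(spec: SyntheticSpec) -> SyntheticBundle:
    """Generate (network, target set, pathway collection, tissue annotation).

    Pathways are mutually disjoint node samples.  The target draws the genes
    named in the overlap plan from their pathways and the rest uniformly from
    the remaining nodes, so overlap-based significance varies across sets.
    Base edge weights are uniform in [0.15, 1.0] (a STRING-like confidence
    spread); planted edges use [0.5, 1.0].  One designated tissue covers
    every planted pathway's nodes; all nodes additionally get a random
    tissue label.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g = _base_graph(spec, rng)
    names = {i: f"G{i:04d}" for i in range(spec.n_nodes)}
    net_graph = nx.Graph()
    net_graph.add_nodes_from(names[i] for i in range(spec.n_nodes))
    for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
        net_graph.add_edge(names[u], names[v],
                           weight=float(rng.uniform(0.15, 1.0)))

    all_nodes = [names[i] for i in range(spec.n_nodes)]
    shuffled = list(all_nodes)
    rng.shuffle(shuffled)
    pathway_sets: list[GeneSet] = []
    cursor = 0
    for pid, size in zip(spec.pathway_ids(), spec.pathway_sizes):
        members = frozenset(shuffled[cursor:cursor + size])
        cursor += size
        pathway_sets.append(GeneSet(set_id=pid, name=f"synthetic pathway {pid}",
                                    members=members))
    pathways = GeneSetCollection(pathway_sets)

    chosen: list[str] = []
    for pid, n_shared in spec.target_overlap:
        members = sorted(pathways[pid].members)
        chosen.extend(str(x) for x in rng.choice(members, size=n_shared, replace=False))
    remaining = [n for n in all_nodes if n not in set(chosen)]
    n_rest = spec.target_size - len(chosen)
    chosen.extend(str(x) for x in rng.choice(remaining, size=n_rest, replace=False))
    target = GeneSet(set_id=TARGET_SET_ID, name="synthetic target",
                     members=frozenset(chosen))

    planted_nodes: set[str] = set()
    for pid, p_conn in spec.planted:
        members = pathways[pid].members
        planted_nodes |= members
        for t in sorted(target.members):
            for v in sorted(members):
                if t == v:
                    continue
                if rng.random() < p_conn:
                    w = float(rng.uniform(0.5, 1.0))
                    if net_graph.has_edge(t, v):
                        net_graph[t][v]["weight"] = max(net_graph[t][v]["weight"], w)
                    else:
                        net_graph.add_edge(t, v, weight=w)

    labels: dict[str, set[str]] = {}
    tissue_pool = [f"tissue{i + 1}" for i in range(spec.n_tissues)]
    for node in all_nodes:
        labels.setdefault(node, set()).add(
            tissue_pool[int(rng.integers(spec.n_tissues))]
        )
    for node in planted_nodes:
        labels[node].add(spec.planted_tissue)
    tissue = TissueAnnotation(labels)

    return SyntheticBundle(
        network=Network(net_graph), target=target, pathways=pathways,
        tissue=tissue, spec=spec,
    )


def write_fixture(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the formats the readers consume.

    Files: ``network.tsv``, ``target.txt``, ``pathways.gmt``, ``tissues.tsv``.
    Output is canonical (sorted), so identical bundles give identical bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": outdir / "network.tsv",
        "target": outdir / "target.txt",
        "gmt": outdir / "pathways.gmt",
        "tissue": outdir / "tissues.tsv",
    }
    wio.write_edge_list(bundle.network, paths["network"])
    wio.write_gene_list(sorted(bundle.target.members), paths["target"])
    wio.write_gmt(bundle.pathways, paths["gmt"])
    wio.write_tissue_table(bundle.tissue, paths["tissue"])
    return paths
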