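"""Readers, writers and validation for networks, gene sets and tissue annotations.

File formats
------------
* Edge list: TSV with 2 or 3 columns (``node_a  node_b  [weight]``); lines
  starting with ``#`` are comments.  Weights must lie in ``(0, 1]`` after the
  optional ``weight_scale`` division (pass ``weight_scale=1000`` for raw
  STRING-style combined scores).
* Gene sets: standard GMT (``set_id TAB description TAB member ...``).
* Target list: plain text, one identifier per line.
* Tissue annotations: TSV with columns ``gene_id  tissue_label``; repeated
  gene ids accumulate labels.

Identifier matching everywhere is exact, case-sensitive string equality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

log = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ValidationError",
    "Network",
    "GeneSet",
    "GeneSetCollection",
    "TissueAnnotation",
    "MappedSet",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_tissue_table",
    "write_tissue_table",
    "map_set",
]


class ParseError(ValueError):
    """A line in an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed input violates a domain invariant."""


@dataclass
class Network:
    """Undirected weighted interaction network over opaque gene identifiers.

    Invariants: no self-loops, no duplicate edges (collapsed by max weight),
    all weights in ``(0, 1]``, node ids non-empty strings.
    """

    graph: nx.Graph

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        extra_nodes: Iterable[str] = (),
    ) -> "Network":
        """Build a network from ``(u, v, weight)`` triples.

        Duplicate edges are collapsed by maximum weight; self-loops are
        dropped with a warning.  ``extra_nodes`` adds isolated nodes (the
        edge-list file format cannot express those).
        """
        g = nx.Graph()
        for u, v, w in edges:
            _validate_node_id(u)
            _validate_node_id(v)
            if u == v:
                log.warning("dropping self-loop on node %r", u)
                continue
            if not (0.0 < w <= 1.0):
                raise ValidationError(f"edge weight {w!r} for {u}-{v} outside (0, 1]")
            if g.has_edge(u, v):
                g[u][v]["weight"] = max(g[u][v]["weight"], float(w))
            else:
                g.add_edge(u, v, weight=float(w))
        for n in extra_nodes:
            _validate_node_id(n)
            g.add_node(n)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def weight(self, u: str, v: str) -> float:
        return float(self.graph[u][v]["weight"])

    def edges(self) -> list[tuple[str, str, float]]:
        """Edges in canonical order: endpoints sorted within the pair, pairs sorted."""
        out = []
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append((a, b, float(data["weight"])))
        out.sort()
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.nodes == other.nodes and self.edges() == other.edges()


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.set_id:
            raise ValidationError("gene set id must be non-empty")
        if not self.members:
            raise ValidationError(f"gene set {self.set_id!r} has no members")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [gs.set_id for gs in self.sets]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate set ids in collection: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for gs in self.sets:
            if gs.set_id == set_id:
                return gs
        raise KeyError(set_id)

    @property
    def set_ids(self) -> list[str]:
        return [gs.set_id for gs in self.sets]


@dataclass
class TissueAnnotation:
    """Mapping from gene identifier to the set of tissue labels it carries."""

    labels: dict[str, set[str]] = field(default_factory=dict)

    def tissues(self) -> list[str]:
        out: set[str] = set()
        for labs in self.labels.values():
            out |= labs
        return sorted(out)

    def genes_for(self, tissue: str) -> set[str]:
        return {g for g, labs in self.labels.items() if tissue in labs}


@dataclass
class MappedSet:
    """A gene set partitioned into network-mapped and unmapped identifiers."""

    origin: GeneSet
    mapped: set[str]
    unmapped: set[str]
    warning: str | None = None

    @property
    def set_id(self) -> str:
        return self.origin.set_id

    @property
    def n_mapped(self) -> int:
        return len(self.mapped)

    @property
    def scorable(self) -> bool:
        return len(self.mapped) > 0


def _validate_node_id(node: object) -> None:
    if not isinstance(node, str) or node == "":
        raise ValidationError(f"invalid node identifier {node!r}")


def read_edge_list(path: str | Path, weight_scale: float | None = None) -> Network:
    """Read a TSV edge list into a :class:`Network`.

    Lines have 2 columns (weight defaults to 1.0) or 3 columns.  Weights are
    divided by ``weight_scale`` when given and must then lie in ``(0, 1]``.
    Duplicate edges collapse by maximum weight; self-loops are dropped with a
    logged warning.
    """
    path = Path(path)
    g = nx.Graph()
    n_selfloops = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                u, v = fields
                w_str = "1.0"
            elif len(fields) == 3:
                u, v, w_str = fields
            else:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            u, v = u.strip(), v.strip()
            if not u or not v:
                raise ParseError(f"{path}:{lineno}: empty node identifier")
            try:
                w = float(w_str)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad weight {w_str!r}") from exc
            if weight_scale is not None:
                w /= weight_scale
            if not (0.0 < w <= 1.0):
                raise ValidationError(
                    f"{path}:{lineno}: weight {w} outside (0, 1] after scaling"
                )
            if u == v:
                n_selfloops += 1
                continue
            if g.has_edge(u, v):
                g[u][v]["weight"] = max(g[u][v]["weight"], w)
            else:
                g.add_edge(u, v, weight=w)
    if n_selfloops:
        log.warning("%s: dropped %d self-loop(s)", path, n_selfloops)
    return Network(g)


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write a network as a canonical, re-readable TSV edge list.

    Weights are printed with 17 significant digits so reading the file back
    reproduces the network exactly.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# node_a\tnode_b\tweight\n")
        for u, v, w in net.edges():
            fh.write(f"{u}\t{v}\t{w:.17g}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set_id TAB description TAB member...), preserving order.

    Members are deduplicated within a set; duplicate set ids raise."""
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            set_id, name = fields[0].strip(), fields[1].strip()
            members = frozenset(m.strip() for m in fields[2:] if m.strip())
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {set_id!r} has no members")
            sets.append(GeneSet(set_id=set_id, name=name, members=members))
    return GeneSetCollection(sets)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.members)]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one identifier per line, '#' comments allowed.

    Order is preserved; duplicates are removed."""
    seen: dict[str, None] = {}
    with Path(path).open() as fh:
        for raw in fh:
            ident = raw.strip()
            if not ident or ident.startswith("#"):
                continue
            seen.setdefault(ident, None)
    return list(seen)


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in genes:
            fh.write(g + "\n")


def read_tissue_table(path: str | Path) -> TissueAnnotation:
    """Read a two-column TSV of (gene_id, tissue_label) pairs."""
    path = Path(path)
    labels: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields")
            gene, tissue = fields[0].strip(), fields[1].strip()
            if not gene or not tissue:
                raise ParseError(f"{path}:{lineno}: empty gene id or tissue label")
            labels.setdefault(gene, set()).add(tissue)
    return TissueAnnotation(labels)


def write_tissue_table(ann: TissueAnnotation, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gene in sorted(ann.labels):
            for tissue in sorted(ann.labels[gene]):
                fh.write(f"{gene}\t{tissue}\n")


def map_set(gs: GeneSet, net: Network, min_mapped: int = 10) -> MappedSet:
    """Partition a gene set into network-mapped and unmapped identifiers.

    If fewer than ``min_mapped`` identifiers map, a warning is attached (the
    computation still proceeds); a set with zero mapped members is not
    scorable.  Degenerate cases are signalled via flags, never exceptions.
    """
    if min_mapped < 1:
        raise ValidationError("min_mapped must be >= 1")
    node_ids = net.nodes
    mapped = {m for m in gs.members if m in node_ids}
    unmapped = set(gs.members) - mapped
    warning = None
    if len(mapped) == 0:
        warning = f"set {gs.set_id!r}: no members map to the network (unscorable)"
        log.warning(warning)
    elif len(mapped) < min_mapped:
        warning = (
            f"set {gs.set_id!r}: only {len(mapped)} of {len(gs.members)} members "
            f"map to the network (recommended minimum {min_mapped})"
        )
        log.warning(warning)
    return MappedSet(origin=gs, mapped=mapped, unmapped=unmapped, warning=warning)
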