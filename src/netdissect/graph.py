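"""Typed ceRNA/PPI graph container.

The integrated network (PPI backbone plus competing-endogenous-RNA edges)
is an undirected simple graph in which every node carries a biological
type — ``lncRNA``, ``diabetes``, ``DR``, ``common`` (associated with both
diseases) or ``other`` — and every edge carries a kind, ``ppi`` or
``cerna``.  A ceRNA edge additionally records the miRNAs whose binding
sites the lncRNA and the coding gene share (the sponging evidence).

A node pair may in principle carry one edge of each kind (an lncRNA that
also appears in the protein interaction data); both are retained and a
node's degree counts both.  Internally the container wraps a
:class:`networkx.MultiGraph` keyed by edge kind, so at most one edge per
(pair, kind) exists.
"""

from __future__ import annotations

import csv
from typing import Iterable, Iterator

import networkx as nx

from .errors import ValidationError

NODE_TYPES = ("lncRNA", "diabetes", "DR", "common", "other")
EDGE_KINDS = ("ppi", "cerna")


class TypedGraph:
    """Undirected simple graph with typed nodes and kinded edges."""

    def __init__(self) -> None:
        self._g = nx.MultiGraph()

    # -- nodes ---------------------------------------------------------

    def add_node(self, node: str, ntype: str = "other") -> None:
        if ntype not in NODE_TYPES:
            raise ValidationError(f"unknown node type {ntype!r}")
        self._g.add_node(node, ntype=ntype)

    def set_type(self, node: str, ntype: str) -> None:
        if node not in self._g:
            raise ValidationError(f"unknown node {node!r}")
        if ntype not in NODE_TYPES:
            raise ValidationError(f"unknown node type {ntype!r}")
        self._g.nodes[node]["ntype"] = ntype

    def node_type(self, node: str) -> str:
        return self._g.nodes[node]["ntype"]

    def node_types(self) -> dict[str, str]:
        return {n: d["ntype"] for n, d in self._g.nodes(data=True)}

    def nodes(self, ntype: str | None = None) -> list[str]:
        if ntype is None:
            return list(self._g.nodes)
        return [n for n, d in self._g.nodes(data=True) if d["ntype"] == ntype]

    def has_node(self, node: str) -> bool:
        return node in self._g

    # -- edges ---------------------------------------------------------

    def add_edge(
        self,
        u: str,
        v: str,
        kind: str = "ppi",
        shared_mirnas: Iterable[str] = (),
    ) -> None:
        """Add an edge; duplicates of the same (pair, kind) merge miRNA lists."""
        if kind not in EDGE_KINDS:
            raise ValidationError(f"unknown edge kind {kind!r}")
        if u == v:
            raise ValidationError(f"self-loop on {u!r} rejected")
        for n in (u, v):
            if n not in self._g:
                self._g.add_node(n, ntype="other")
        mirnas = tuple(sorted(set(shared_mirnas)))
        if kind == "cerna":
            n_lnc = sum(self.node_type(n) == "lncRNA" for n in (u, v))
            if n_lnc != 1:
                raise ValidationError(
                    f"cerna edge {u!r}-{v!r} must join exactly one lncRNA "
                    f"(found {n_lnc})"
                )
        if self._g.has_edge(u, v, key=kind):
            old = self._g.edges[u, v, kind].get("shared_mirnas", ())
            merged = tuple(sorted(set(old) | set(mirnas)))
            self._g.edges[u, v, kind]["shared_mirnas"] = merged
            return
        self._g.add_edge(u, v, key=kind, kind=kind, shared_mirnas=mirnas)

    def has_edge(self, u: str, v: str, kind: str | None = None) -> bool:
        if kind is None:
            return self._g.has_edge(u, v)
        return self._g.has_edge(u, v, key=kind)

    def edges(
        self, kind: str | None = None
    ) -> Iterator[tuple[str, str, str, tuple[str, ...]]]:
        """Yield (u, v, kind, shared_mirnas) with u < v for determinism."""
        for u, v, k, d in self._g.edges(keys=True, data=True):
            if kind is not None and k != kind:
                continue
            a, b = sorted((u, v))
            yield a, b, k, tuple(d.get("shared_mirnas", ()))

    def shared_mirnas(self, u: str, v: str) -> tuple[str, ...]:
        return tuple(self._g.edges[u, v, "cerna"].get("shared_mirnas", ()))

    def degree(self, node: str) -> int:
        """Number of incident edges, ppi and cerna alike."""
        return self._g.degree(node)

    def degrees(self) -> dict[str, int]:
        return dict(self._g.degree())

    def neighbors(self, node: str, kind: str | None = None) -> list[str]:
        if kind is None:
            return sorted(self._g.neighbors(node))
        return sorted(
            {v for _, v, k in self._g.edges(node, keys=True) if k == kind}
        )

    # -- counts --------------------------------------------------------

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self, kind: str | None = None) -> int:
        if kind is None:
            return self._g.number_of_edges()
        return sum(1 for _ in self.edges(kind))

    # -- derived views -------------------------------------------------

    def simple_graph(self) -> nx.Graph:
        """Collapse parallel (ppi, cerna) edges into one; used for path
        and neighbourhood based metrics where multiplicity is irrelevant."""
        g = nx.Graph()
        g.add_nodes_from(self._g.nodes)
        g.add_edges_from((u, v) for u, v, _k in self._g.edges(keys=True))
        return g

    def subgraph(self, nodes: Iterable[str]) -> "TypedGraph":
        keep = set(nodes)
        out = TypedGraph()
        for n in self._g.nodes:
            if n in keep:
                out.add_node(n, self.node_type(n))
        for u, v, k, m in self.edges():
            if u in keep and v in keep:
                out.add_edge(u, v, k, m)
        return out

    def copy(self) -> "TypedGraph":
        return self.subgraph(self._g.nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TypedGraph):
            return NotImplemented
        return (
            self.node_types() == other.node_types()
            and sorted(self.edges()) == sorted(other.edges())
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TypedGraph({self.number_of_nodes()} nodes, "
            f"{self.number_of_edges()} edges)"
        )

    # -- serialization -------------------------------------------------

    def to_graphml(self, path: str) -> None:
        g = nx.MultiGraph()
        for n, t in self.node_types().items():
            g.add_node(n, ntype=t)
        for u, v, k, m in self.edges():
            g.add_edge(u, v, key=k, kind=k, shared_mirnas=",".join(m))
        nx.write_graphml(g, path)

    @classmethod
    def from_graphml(cls, path: str) -> "TypedGraph":
        raw = nx.read_graphml(path, force_multigraph=True)
        out = cls()
        for n, d in raw.nodes(data=True):
            out.add_node(str(n), d.get("ntype", "other"))
        for u, v, d in raw.edges(data=True):
            m = [s for s in d.get("shared_mirnas", "").split(",") if s]
            out.add_edge(str(u), str(v), d.get("kind", "ppi"), m)
        return out

    def to_tsv(self, edge_path: str, node_path: str | None = None) -> None:
        with open(edge_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["node_a", "node_b", "kind", "shared_mirnas"])
            for u, v, k, m in sorted(self.edges()):
                w.writerow([u, v, k, ",".join(m)])
        if node_path is not None:
            with open(node_path, "w", newline="") as fh:
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                w.writerow(["node", "type"])
                for n in sorted(self._g.nodes):
                    w.writerow([n, self.node_type(n)])

    @classmethod
    def from_tsv(cls, edge_path: str, node_path: str | None = None) -> "TypedGraph":
        out = cls()
        if node_path is not None:
            with open(node_path, newline="") as fh:
                rd = csv.DictReader(fh, delimiter="\t")
                for row in rd:
                    out.add_node(row["node"], row["type"])
        with open(edge_path, newline="") as fh:
            rd = csv.DictReader(fh, delimiter="\t")
            for row in rd:
                m = [s for s in (row.get("shared_mirnas") or "").split(",") if s]
                out.add_edge(row["node_a"], row["node_b"], row["kind"], m)
        return out
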