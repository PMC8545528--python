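"""Molecular Complex Detection (MCODE) implemented from scratch.

The canonical three-stage formulation: (1) vertex weighting — each node
is scored by the density of the highest k-core of its closed
neighbourhood times that core's k; (2) complex prediction — seeds are
taken in descending weight order and grown outward, admitting neighbours
whose weight exceeds the seed weight times (1 - node score cutoff);
(3) post-processing — the "haircut" iteratively strips members with a
single intra-complex edge, and complexes whose induced minimum core falls
below the k-core threshold are discarded.  Complexes are disjoint
(first-claim wins in seed order) and scored density x member count.

Study parameters: k-core = 2, node score cutoff = 0.2, max depth = 100,
haircut on, fluff off; the top 5 complexes by score are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import ConfigError
from .graph import TypedGraph


@dataclass(frozen=True)
class McodeParams:
    k_core: int = 2
    node_score_cutoff: float = 0.2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.1

    def validate(self) -> None:
        if self.k_core < 2:
            raise ConfigError("k_core must be >= 2")
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ConfigError("node_score_cutoff must lie in [0, 1]")
        if self.max_depth < 1:
            raise ConfigError("max_depth must be >= 1")


@dataclass(frozen=True)
class ModuleResult:
    """A detected complex: sorted members, density x size score, seed."""

    members: tuple[str, ...]
    score: float
    seed: str

    @property
    def size(self) -> int:
        return len(self.members)


def _as_simple(g: TypedGraph | nx.Graph) -> nx.Graph:
    return g.simple_graph() if isinstance(g, TypedGraph) else g


def k_core_decomposition(g: TypedGraph | nx.Graph) -> dict[str, int]:
    """Core number per node by iterative minimum-degree peeling.

    core(v) is the largest k such that v survives repeatedly deleting all
    nodes of degree < k.  Isolated nodes get core 0.
    """
    simple = _as_simple(g)
    degree = dict(simple.degree())
    neigh = {v: set(simple.neighbors(v)) for v in simple.nodes}
    core: dict[str, int] = {}
    remaining = set(simple.nodes)
    k = 0
    while remaining:
        peel = [v for v in remaining if degree[v] <= k]
        while peel:
            nxt = []
            for v in peel:
                if v not in remaining:
                    continue
                core[v] = k
                remaining.discard(v)
                for u in neigh[v]:
                    if u in remaining:
                        degree[u] -= 1
                        if degree[u] <= k:
                            nxt.append(u)
            peel = nxt
        k += 1
    return core


def _density(sub: nx.Graph) -> float:
    n = sub.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * sub.number_of_edges() / (n * (n - 1))


def vertex_weights(g: TypedGraph | nx.Graph) -> dict[str, float]:
    """MCODE vertex weight: k_max x density of the highest k-core of the
    closed neighbourhood; zero for isolated nodes."""
    simple = _as_simple(g)
    weights: dict[str, float] = {}
    for v in simple.nodes:
        nbrs = set(simple.neighbors(v))
        if not nbrs:
            weights[v] = 0.0
            continue
        closed = simple.subgraph(nbrs | {v})
        cores = k_core_decomposition(closed)
        k_max = max(cores.values())
        top = closed.subgraph([u for u, c in cores.items() if c >= k_max])
        weights[v] = k_max * _density(top)
    return weights


def _haircut(simple: nx.Graph, members: set[str]) -> set[str]:
    members = set(members)
    while True:
        sub = simple.subgraph(members)
        strip = [v for v in members if sub.degree(v) == 1]
        if not strip:
            return members
        members -= set(strip)


def _fluff(simple: nx.Graph, members: set[str], density_cutoff: float) -> set[str]:
    extra = set()
    for v in sorted(members):
        for u in simple.neighbors(v):
            if u in members or u in extra:
                continue
            closed = simple.subgraph(set(simple.neighbors(u)) | {u})
            if _density(closed) > density_cutoff:
                extra.add(u)
    return members | extra


def predict_complexes(
    g: TypedGraph | nx.Graph, params: McodeParams = McodeParams()
) -> list[ModuleResult]:
    """Seeded expansion over the vertex-weighted graph.

    Neighbours join a growing complex iff their weight exceeds the seed
    weight times (1 - cutoff) and they are not claimed by an earlier
    complex; expansion is breadth-first to ``max_depth``.  After the
    haircut, a complex survives only if its induced minimum core number
    reaches ``k_core``.
    """
    params.validate()
    simple = _as_simple(g)
    if simple.number_of_nodes() == 0:
        return []
    weights = vertex_weights(simple)
    order = sorted(simple.nodes, key=lambda v: (-weights[v], v))
    claimed: set[str] = set()   # members of kept complexes
    examined: set[str] = set()  # nodes already used as/absorbed by a seed run
    results: list[ModuleResult] = []
    for seed in order:
        if seed in claimed or seed in examined:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for v in frontier:
                for u in sorted(simple.neighbors(v)):
                    if u in members or u in claimed:
                        continue
                    if weights[u] > threshold:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
            depth += 1
        examined |= members
        if params.haircut:
            members = _haircut(simple, members)
        if params.fluff:
            members = _fluff(simple, members, params.fluff_density)
        if not members:
            continue
        induced = simple.subgraph(members)
        cores = k_core_decomposition(induced)
        if min(cores.values()) < params.k_core:
            continue
        score = _density(induced) * len(members)
        results.append(
            ModuleResult(tuple(sorted(members)), float(score), seed)
        )
        claimed |= set(members)
    return results


def rank_modules(
    modules: list[ModuleResult], top_n: int = 5
) -> list[ModuleResult]:
    """Top-n complexes by score desc, then size desc, then smallest id."""
    ranked = sorted(
        modules, key=lambda m: (-m.score, -m.size, m.members[0])
    )
    return ranked[:max(0, top_n)]


def modules_json(modules: list[ModuleResult]) -> list[dict]:
    return [
        {"members": list(m.members), "score": m.score, "seed": m.seed,
         "size": m.size}
        for m in modules
    ]
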