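"""Merging raw contigs into long repeats via paths in the contig graph.

The contig graph usually contains cycles (repeats within repeats,
tandem structure), so exhaustive path enumeration is impractical.
Instead the graph is condensed to its strongly connected components
(the condensation is acyclic by construction), each component's nodes
are arranged in a near-topological linear order, and greedy walks
following that order emit maximal paths.  Each path is concatenated
into one assembled repeat using the stored junction overlaps.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .config import PipelineConfig
from .graph import ContigGraph, Overlap


@dataclass
class SccPartition:
    """Partition of graph nodes into strongly connected components."""

    components: list[set]
    component_of: dict

    def __len__(self) -> int:
        return len(self.components)


@dataclass
class AssembledRepeat:
    """The merged sequence of one maximal contig-graph path."""

    id: str
    sequence: str
    path: list[tuple[str, str]]  # (contig id, orientation)
    junctions: list[Overlap] = field(default_factory=list)
    mean_coverage: float | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


def find_sccs(graph: nx.DiGraph) -> SccPartition:
    """Strongly connected components, ordered by smallest member id."""
    components = sorted(
        (set(c) for c in nx.strongly_connected_components(graph)),
        key=lambda c: min(c),
    )
    component_of = {node: i for i, comp in enumerate(components) for node in comp}
    return SccPartition(components=components, component_of=component_of)


def condense(graph: nx.DiGraph, sccs: SccPartition) -> nx.DiGraph:
    """Acyclic component graph: edge C1 -> C2 iff some original edge crosses."""
    dag = nx.DiGraph()
    dag.add_nodes_from(range(len(sccs.components)))
    for u, v in graph.edges():
        cu, cv = sccs.component_of[u], sccs.component_of[v]
        if cu != cv:
            dag.add_edge(cu, cv)
    if not nx.is_directed_acyclic_graph(dag):
        raise RuntimeError("condensation contains a cycle; SCC computation is broken")
    return dag


def linear_order(subgraph: nx.DiGraph) -> list:
    """Kahn-style ordering tolerant of cycles.

    Zero-in-degree candidates are taken smallest id first.  When every
    remaining node sits on a cycle, the smallest-id remaining node has
    its incoming edges discarded and the sort continues, so the result
    is a true topological order whenever the subgraph is acyclic.
    """
    indeg = {v: subgraph.in_degree(v) for v in subgraph.nodes()}
    remaining = set(indeg)
    ready = [v for v in indeg if indeg[v] == 0]
    heapq.heapify(ready)
    order = []
    while remaining:
        while ready and ready[0] not in remaining:
            heapq.heappop(ready)
        if not ready:
            breaker = min(remaining)
            indeg[breaker] = 0
            heapq.heappush(ready, breaker)
            continue
        v = heapq.heappop(ready)
        remaining.discard(v)
        order.append(v)
        for w in subgraph.successors(v):
            if w in remaining:
                indeg[w] -= 1
                if indeg[w] <= 0:
                    heapq.heappush(ready, w)
    return order


def enumerate_paths(graph: nx.DiGraph, condensation: nx.DiGraph,
                    orders: Sequence[list]) -> list[list]:
    """Greedy maximal paths following the global near-topological order.

    Walks start from every in-degree-0 node, then from any node not yet
    covered (so every node appears in at least one path).  At each step
    the out-edge to the nearest subsequent node in the linear order is
    preferred (falling back to the nearest node overall, ties to the
    smallest id); nodes are never revisited within one path.  Paths that
    are contiguous subsequences of another emitted path are removed.
    """
    rank: dict = {}
    for comp_index in nx.lexicographical_topological_sort(condensation):
        for node in orders[comp_index]:
            rank[node] = len(rank)

    def walk(start) -> list:
        path = [start]
        in_path = {start}
        cur = start
        while True:
            succs = [s for s in graph.successors(cur) if s not in in_path]
            if not succs:
                break
            ahead = [s for s in succs if rank[s] > rank[cur]]
            pool = ahead if ahead else succs
            cur = min(pool, key=lambda s: (rank[s], s))
            path.append(cur)
            in_path.add(cur)
        return path

    paths: list[list] = []
    covered: set = set()
    starts = sorted((n for n in graph.nodes() if graph.in_degree(n) == 0),
                    key=lambda n: (rank[n], n))
    for start in starts:
        p = walk(start)
        paths.append(p)
        covered.update(p)
    uncovered = sorted(set(graph.nodes()) - covered, key=lambda n: (rank[n], n))
    while uncovered:
        p = walk(uncovered[0])
        paths.append(p)
        covered.update(p)
        uncovered = [n for n in uncovered if n not in covered]

    return _remove_subpaths(paths)


def _remove_subpaths(paths: list[list]) -> list[list]:
    """Drop any path that is a contiguous subsequence of another."""
    unique: list[tuple] = []
    seen = set()
    for p in paths:
        t = tuple(p)
        if t not in seen:
            seen.add(t)
            unique.append(t)

    def is_subpath(small: tuple, big: tuple) -> bool:
        if len(small) > len(big):
            return False
        return any(big[i:i + len(small)] == small
                   for i in range(len(big) - len(small) + 1))

    kept = [
        p for p in unique
        if not any(p is not q and is_subpath(p, q) for q in unique)
    ]
    return [list(p) for p in kept]


def merge_path(path: Sequence, cgraph: ContigGraph, repeat_id: str) -> AssembledRepeat:
    """Concatenate a path's contigs, eliding each junction overlap.

    The merged sequence keeps the predecessor's bases across mismatching
    junction columns: each successor contributes only its suffix beyond
    the aligned prefix.
    """
    first = cgraph.contigs[path[0]]
    sequence = first.sequence
    junctions: list[Overlap] = []
    for prev, nxt in zip(path, path[1:]):
        data = cgraph.graph.get_edge_data(prev, nxt)
        if data is None:
            raise RuntimeError(f"missing junction record for {prev} -> {nxt}")
        ov: Overlap = data["overlap"]
        sequence += cgraph.contigs[nxt].sequence[ov.length:]
        junctions.append(ov)
    oriented_path = [(cid, cgraph.orientation.get(cid, "+")) for cid in path]
    return AssembledRepeat(id=repeat_id, sequence=sequence,
                           path=oriented_path, junctions=junctions)


def assemble_repeats(cgraph: ContigGraph) -> list[AssembledRepeat]:
    """Full scaffolding stage: SCCs, condensation, ordering, paths, merging."""
    graph = cgraph.graph
    if graph.number_of_nodes() == 0:
        return []
    sccs = find_sccs(graph)
    dag = condense(graph, sccs)
    orders = [linear_order(graph.subgraph(comp)) for comp in sccs.components]
    paths = enumerate_paths(graph, dag, orders)
    return [merge_path(p, cgraph, f"rep{i:04d}") for i, p in enumerate(paths)]
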