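import networkx as nx
import numpy as np
import pytest

import repweaver as rw
from repweaver.assembly import RawContig
from repweaver.graph import ContigGraph, Overlap
from repweaver.scaffold import (condense, enumerate_paths, find_sccs,
                                linear_order, merge_path)

from conftest import random_dna


def reachability_partition(graph: nx.DiGraph):
    """Oracle: SCCs via all-pairs mutual reachability."""
    nodes = sorted(graph.nodes())
    reach = {u: set(nx.descendants(graph, u)) | {u} for u in nodes}
    comps = []
    assigned = set()
    for u in nodes:
        if u in assigned:
            continue
        comp = {v for v in nodes if v in reach[u] and u in reach[v]}
        comps.append(comp)
        assigned |= comp
    return comps


def random_digraph(rng, n, p=0.25):
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < p:
                g.add_edge(u, v)
    return g


def plan(graph):
    sccs = find_sccs(graph)
    dag = condense(graph, sccs)
    orders = [linear_order(graph.subgraph(c)) for c in sccs.components]
    return enumerate_paths(graph, dag, orders)


# ----------------------------------------------------------------- SCC / DAG

def test_sccs_of_dag_are_singletons():
    g = nx.DiGraph([("a", "b"), ("b", "c"), ("a", "d")])
    part = find_sccs(g)
    assert all(len(c) == 1 for c in part.components)
    assert len(part) == 4


def test_scc_three_cycle():
    g = nx.DiGraph([("a", "b"), ("b", "c"), ("c", "a")])
    part = find_sccs(g)
    assert part.components == [{"a", "b", "c"}]


def test_two_cycles_with_bridge():
    g = nx.DiGraph([("a", "b"), ("b", "a"), ("c", "d"), ("d", "c"), ("b", "c")])
    part = find_sccs(g)
    assert sorted(map(sorted, part.components)) == [["a", "b"], ["c", "d"]]
    dag = condense(g, part)
    assert dag.number_of_edges() == 1


@pytest.mark.parametrize("seed", range(15))
def test_sccs_match_reachability_oracle(seed):
    rng = np.random.default_rng(seed)
    g = random_digraph(rng, int(rng.integers(2, 11)))
    got = sorted(map(sorted, find_sccs(g).components))
    expected = sorted(map(sorted, reachability_partition(g)))
    assert got == expected
    condense(g, find_sccs(g))  # must not raise (acyclic by construction)


def test_condense_preserves_structure():
    g = nx.DiGraph()
    g.add_nodes_from("abc")
    assert condense(g, find_sccs(g)).number_of_edges() == 0
    path = nx.DiGraph([("a", "b"), ("b", "c")])
    dag = condense(path, find_sccs(path))
    assert dag.number_of_nodes() == 3 and dag.number_of_edges() == 2


# -------------------------------------------------------------- linear order

def test_linear_order_simple_chain():
    g = nx.DiGraph([("c", "a"), ("a", "b")])
    assert linear_order(g) == ["c", "a", "b"]


def test_linear_order_breaks_two_cycle_by_smallest_id():
    g = nx.DiGraph([("a", "b"), ("b", "a")])
    assert linear_order(g) == ["a", "b"]


@pytest.mark.parametrize("seed", range(10))
def test_linear_order_topological_on_random_dags(seed):
    rng = np.random.default_rng(50 + seed)
    n = int(rng.integers(2, 9))
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(u + 1, n):
            if rng.random() < 0.4:
                g.add_edge(u, v)
    order = linear_order(g)
    position = {v: i for i, v in enumerate(order)}
    assert sorted(order) == list(range(n))
    for u, v in g.edges():
        assert position[u] < position[v]


# ------------------------------------------------------------------ walking

def test_paths_edgeless_graph_singletons():
    g = nx.DiGraph()
    g.add_nodes_from("abc")
    assert sorted(plan(g)) == [["a"], ["b"], ["c"]]


def test_paths_simple_chain_single_maximal_path():
    g = nx.DiGraph([("a", "b"), ("b", "c")])
    assert plan(g) == [["a", "b", "c"]]


def test_paths_fork_prefers_nearest_in_order():
    g = nx.DiGraph([("a", "b"), ("a", "c")])
    paths = plan(g)
    assert ["a", "b"] in paths and ["c"] in paths
    assert len(paths) == 2


@pytest.mark.parametrize("seed", range(30))
def test_path_invariants_on_random_graphs(seed):
    rng = np.random.default_rng(200 + seed)
    g = random_digraph(rng, int(rng.integers(1, 13)))
    paths = plan(g)
    covered = set()
    tuples = [tuple(p) for p in paths]
    for p in paths:
        assert len(p) == len(set(p))                # distinct nodes
        for u, v in zip(p, p[1:]):
            assert g.has_edge(u, v)                 # consecutive are edges
        covered.update(p)
    assert covered == set(g.nodes())                # full node coverage
    for a in tuples:                                # pairwise non-sub-path
        for b in tuples:
            if a is b:
                continue
            assert not any(b[i:i + len(a)] == a
                           for i in range(len(b) - len(a) + 1))


# ------------------------------------------------------------------- merging

def _cgraph(contigs, edges):
    g = nx.DiGraph()
    g.add_nodes_from(c.id for c in contigs)
    for u, v, ov in edges:
        g.add_edge(u, v, overlap=ov, support=1, expected=True)
    return ContigGraph(graph=g, contigs={c.id: c for c in contigs})


def test_merge_singleton_path():
    c = RawContig("c0", "ACGTACGT", 3)
    rep = merge_path(["c0"], _cgraph([c], []), "rep0")
    assert rep.sequence == "ACGTACGT"
    assert rep.path == [("c0", "+")]


def test_merge_exact_overlap():
    c1 = RawContig("c0", "AAAACCCC", 4)
    c2 = RawContig("c1", "CCCCGGGG", 4)
    ov = Overlap("c0", "c1", 4, 0, "+")
    rep = merge_path(["c0", "c1"], _cgraph([c1, c2], [("c0", "c1", ov)]), "r")
    assert rep.sequence == "AAAACCCCGGGG"


def test_merge_keeps_predecessor_base_at_mismatch():
    rng = np.random.default_rng(60)
    junction = random_dna(rng, 20)
    mutated = ("T" if junction[5] != "T" else "G")
    other = junction[:5] + mutated + junction[6:]
    left = random_dna(rng, 40) + junction
    right = other + random_dna(rng, 40)
    c1, c2 = RawContig("c0", left, 5), RawContig("c1", right, 5)
    ov = Overlap("c0", "c1", 20, 1, "+")
    rep = merge_path(["c0", "c1"], _cgraph([c1, c2], [("c0", "c1", ov)]), "r")
    assert rep.length == len(left) + len(right) - 20
    assert rep.sequence[len(left) - 15] == junction[5]  # predecessor wins


def test_merge_missing_junction_is_internal_error():
    c1, c2 = RawContig("c0", "AAAACCCC", 4), RawContig("c1", "CCCCGGGG", 4)
    with pytest.raises(RuntimeError, match="junction"):
        merge_path(["c0", "c1"], _cgraph([c1, c2], []), "r")
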