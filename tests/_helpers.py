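"""Shared test utilities: independent oracles and benchmark constructors."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from minetkit.matrix import IndexMatrix
from minetkit.seedset import MetaboliteGraph


def planted_block_matrix(
    seed: int,
    n_blocks: int = 10,
    block_size: int = 16,
    signal: tuple[float, float] = (0.8, 1.0),
    noise: tuple[float, float] = (0.0, 0.5),
) -> IndexMatrix:
    """Symmetric [0,1] matrix with dense high-value diagonal blocks on a
    low-value noise background; the signal/noise gap forces the RMT
    transition at the noise support boundary."""
    rng = np.random.default_rng(seed)
    n = n_blocks * block_size
    a = rng.uniform(*noise, size=(n, n))
    for k in range(n_blocks):
        sl = slice(k * block_size, (k + 1) * block_size)
        a[sl, sl] = rng.uniform(*signal, size=(block_size, block_size))
    a = np.triu(a, 1)
    a = a + a.T
    ids = [f"m{i:03d}" for i in range(n)]
    return IndexMatrix(ids=ids, values=a, symmetric=True, kind="similarity")


def block_of(node_id: str, block_size: int = 16) -> int:
    return int(node_id[1:]) // block_size


def random_digraph(seed: int, max_nodes: int = 30, p: float = 0.12) -> MetaboliteGraph:
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_nodes + 1))
    g = nx.gnp_random_graph(n, p, seed=seed, directed=True)
    g = nx.relabel_nodes(g, {i: f"v{i:02d}" for i in g.nodes})
    return MetaboliteGraph(graph=g, origin_model=f"rand{seed}")


def brute_force_sccs(graph: MetaboliteGraph) -> list[frozenset[str]]:
    """O(n^3) SCCs from pairwise mutual reachability (pure BFS)."""
    g = graph.graph
    nodes = sorted(g.nodes)
    reach = {v: _bfs_reachable(g, v) for v in nodes}
    comps: list[frozenset[str]] = []
    assigned: set[str] = set()
    for v in nodes:
        if v in assigned:
            continue
        comp = frozenset(
            u for u in nodes if u in reach[v] and v in reach[u]
        )
        comps.append(comp)
        assigned |= comp
    return sorted(comps, key=min)


def _bfs_reachable(g: nx.DiGraph, start: str) -> set[str]:
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for w in g.successors(v):
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


def brute_force_centralities(g: nx.Graph):
    """Betweenness/stress by explicit enumeration of all shortest paths."""
    nodes = sorted(g.nodes)
    betweenness = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            if through:
                stress[v] += through
                betweenness[v] += through / len(paths)
    return betweenness, stress
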