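"""Topological analysis of the metabolic interaction network.

Global properties, node centralities (degree, betweenness, stress, local
clustering), greedy-modularity module detection, within-module degree
z-score (z_i) / among-module participation (P_i) hub classification,
attribute merging and network intersection. All topology is computed on
the binarized network; weights, when present, survive only as edge
annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Guimerà–Amaral style role thresholds.
DEFAULT_Z_THRESHOLD = 2.5
DEFAULT_P_THRESHOLD = 0.62

ROLE_PERIPHERAL = "peripheral"
ROLE_MODULE_HUB = "module hub"
ROLE_CONNECTOR = "connector"
ROLE_NETWORK_HUB = "network hub"


@dataclass
class GlobalProperties:
    n_nodes: int
    n_edges: int
    average_degree: float
    density: float
    average_clustering_coefficient: float
    average_path_length: float
    n_components: int
    modularity: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"property": list(vars(self)), "value": list(vars(self).values())}
        )


@dataclass
class ModulePartition:
    modules: list[list[str]]
    module_of: dict[str, int]
    modularity: float


def _check_simple(net: nx.Graph) -> None:
    if any(u == v for u, v in net.edges):
        raise ValidationError("network contains self-loops")


def global_properties(net: nx.Graph, seed: int = 0) -> GlobalProperties:
    """Whole-network summary; path length is averaged within the largest
    connected component."""
    _check_simple(net)
    n = net.number_of_nodes()
    if n < 2:
        raise ValidationError("need ≥2 nodes for global properties")
    m = net.number_of_edges()
    density = 2.0 * m / (n * (n - 1))
    clustering = nx.average_clustering(net) if m else 0.0
    components = list(nx.connected_components(net))
    largest = max(components, key=len)
    if len(largest) > 1:
        apl = nx.average_shortest_path_length(net.subgraph(largest))
    else:
        apl = 0.0
    if len(components) > 1:
        logger.info(
            "network is disconnected (%d components); path length computed "
            "on the largest (%d nodes)", len(components), len(largest),
        )
    modularity = detect_modules(net, seed=seed).modularity if m else float("nan")
    return GlobalProperties(
        n_nodes=n,
        n_edges=m,
        average_degree=2.0 * m / n,
        density=density,
        average_clustering_coefficient=clustering,
        average_path_length=apl,
        n_components=len(components),
        modularity=modularity,
    )


def _shortest_path_counts(net: nx.Graph):
    """All-pairs shortest-path lengths and path counts (BFS per source)."""
    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in nodes:
        si = index[s]
        dist[si, si] = 0
        sigma[si, si] = 1
        frontier = [s]
        d = 0
        while frontier:
            nxt = []
            for v in frontier:
                for w in net[v]:
                    wi = index[w]
                    if np.isinf(dist[si, wi]):
                        dist[si, wi] = d + 1
                        nxt.append(w)
                    if dist[si, wi] == d + 1:
                        sigma[si, wi] += sigma[si, index[v]]
            frontier = nxt
            d += 1
    return nodes, dist, sigma


def node_centralities(net: nx.Graph, normalized: bool = False) -> pd.DataFrame:
    """Per-node degree, betweenness, stress and local clustering.

    Betweenness and stress are raw pair sums by default; ``normalized``
    divides both by the number of ordered node pairs excluding the node
    ((n−1)(n−2) for undirected input handled as pair count (n−1)(n−2)/2).
    """
    _check_simple(net)
    nodes, dist, sigma = _shortest_path_counts(net)
    n = len(nodes)
    betweenness = nx.betweenness_centrality(net, normalized=False)

    stress = {}
    for vi, v in enumerate(nodes):
        dv = dist[:, vi][:, None] + dist[vi, :][None, :]
        on_path = (dv == dist) & np.isfinite(dist)
        counts = sigma[:, vi][:, None] * sigma[vi, :][None, :]
        counts = np.where(on_path, counts, 0.0)
        counts[vi, :] = 0.0
        counts[:, vi] = 0.0
        np.fill_diagonal(counts, 0.0)
        stress[v] = float(np.triu(counts, k=1).sum())

    clustering = nx.clustering(net)
    scale = 1.0
    if normalized and n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
    df = pd.DataFrame(
        {
            "node": nodes,
            "degree": [net.degree(v) for v in nodes],
            "betweenness": [betweenness[v] * scale for v in nodes],
            "stress": [stress[v] * scale for v in nodes],
            "clustering_coefficient": [clustering[v] for v in nodes],
        }
    )
    return df


def detect_modules(net: nx.Graph, seed: int = 0) -> ModulePartition:
    """Greedy modularity maximisation (deterministic; node-id tie-break).

    ``seed`` is accepted for interface stability; the greedy algorithm is
    deterministic for a given graph.
    """
    _check_simple(net)
    if net.number_of_edges() < 1:
        raise ValidationError("module detection needs ≥1 edge")
    # copy with sorted nodes so community iteration order is reproducible
    g = nx.Graph()
    g.add_nodes_from(sorted(net.nodes))
    g.add_edges_from(sorted(tuple(sorted(e)) for e in net.edges))
    communities = nx.community.greedy_modularity_communities(g)
    modules = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    module_of = {v: i for i, mod in enumerate(modules) for v in mod}
    q = nx.community.modularity(g, [set(m) for m in modules])
    return ModulePartition(modules=modules, module_of=module_of, modularity=q)


def _role(z: float, p: float, z_threshold: float, p_threshold: float) -> str:
    if z > z_threshold and p > p_threshold:
        return ROLE_NETWORK_HUB
    if z > z_threshold:
        return ROLE_MODULE_HUB
    if p > p_threshold:
        return ROLE_CONNECTOR
    return ROLE_PERIPHERAL


def zi_pi(
    net: nx.Graph,
    partition: ModulePartition,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Within-module degree z-score and among-module participation.

    z_i compares a node's within-module degree with the distribution over
    its module (population sd; z=0 when the sd is 0). P_i = 1 − Σ_s
    (k_is/k_i)². Roles follow the (z*, P*) thresholds."""
    missing = set(net.nodes) - set(partition.module_of)
    if missing:
        raise ValidationError(f"partition misses nodes: {sorted(missing)}")
    nodes = sorted(net.nodes)
    within = {}
    for v in nodes:
        mod = partition.module_of[v]
        within[v] = sum(1 for w in net[v] if partition.module_of[w] == mod)
    stats_by_module = {}
    for i, mod_nodes in enumerate(partition.modules):
        ks = np.array([within[v] for v in mod_nodes if v in within])
        stats_by_module[i] = (float(ks.mean()), float(ks.std(ddof=0))) if ks.size else (0.0, 0.0)

    rows = []
    for v in nodes:
        k = net.degree(v)
        mod = partition.module_of[v]
        mean, sd = stats_by_module[mod]
        z = (within[v] - mean) / sd if sd > 0 else 0.0
        if k > 0:
            per_module: dict[int, int] = {}
            for w in net[v]:
                mw = partition.module_of[w]
                per_module[mw] = per_module.get(mw, 0) + 1
            p = 1.0 - sum((c / k) ** 2 for c in per_module.values())
        else:
            p = 0.0
        rows.append(
            {
                "node": v,
                "module": mod,
                "within_module_degree": within[v],
                "z_i": z,
                "P_i": p,
                "role": _role(z, p, z_threshold, p_threshold),
            }
        )
    return pd.DataFrame(rows)


def merge_attributes(
    centralities: pd.DataFrame,
    zipi: pd.DataFrame,
    taxonomy: pd.DataFrame | str | Path | None = None,
) -> pd.DataFrame:
    """Left-join node centralities, module/role attributes and an optional
    taxonomy table whose first column holds node ids."""
    for name, df in (("centralities", centralities), ("zi_pi", zipi)):
        if df["node"].duplicated().any():
            raise ValidationError(f"duplicate node ids in {name} table")
    merged = centralities.merge(
        zipi, on="node", how="left", suffixes=("", "_zipi")
    )
    if taxonomy is not None:
        if not isinstance(taxonomy, pd.DataFrame):
            taxonomy = pd.read_csv(taxonomy, sep="\t")
        taxonomy = taxonomy.rename(columns={taxonomy.columns[0]: "node"})
        taxonomy["node"] = taxonomy["node"].astype(str)
        if taxonomy["node"].duplicated().any():
            raise ValidationError("duplicate node ids in taxonomy table")
        unmatched = (~taxonomy["node"].isin(merged["node"])).sum()
        if unmatched:
            logger.info("%d taxonomy row(s) match no network node", unmatched)
        merged = merged.merge(
            taxonomy, on="node", how="left", suffixes=("", "_taxonomy")
        )
    return merged


def intersect_networks(a: nx.Graph, b: nx.Graph) -> nx.Graph:
    """Subnetwork of the common edges; nodes are endpoints of kept edges."""
    _check_simple(a)
    _check_simple(b)
    edges_a = {frozenset(e) for e in a.edges}
    edges_b = {frozenset(e) for e in b.edges}
    common = edges_a & edges_b
    g = nx.Graph()
    for e in sorted(tuple(sorted(e)) for e in common):
        g.add_edge(*e)
    if not common:
        logger.warning("networks share no edges; intersection is empty")
    return g


def edge_list(net: nx.Graph) -> pd.DataFrame:
    rows = sorted(tuple(sorted(e)) for e in net.edges)
    return pd.DataFrame(rows, columns=["source", "target"])


def adjacency_frame(net: nx.Graph) -> pd.DataFrame:
    nodes = sorted(net.nodes)
    mat = nx.to_numpy_array(net, nodelist=nodes, weight=None)
    return pd.DataFrame(mat.astype(int), index=nodes, columns=nodes)
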