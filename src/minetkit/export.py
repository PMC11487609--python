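"""Visualization-oriented exports: the directed microbe–metabolite
bipartite network built from transferable metabolites, and ordered
heatmap data for distance matrices."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .matrix import IndexMatrix
from .phylomint import PTMRecord

logger = logging.getLogger(__name__)

#: Prefix keeping metabolite node ids disjoint from model ids.
METABOLITE_NODE_PREFIX = "met:"


@dataclass
class BipartiteNetwork:
    graph: nx.DiGraph  # donor -> metabolite -> receptor
    node_table: pd.DataFrame  # id, type, name

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "edge_type": "production" if v.startswith(METABOLITE_NODE_PREFIX)
                else "uptake",
            }
            for u, v in sorted(self.graph.edges)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "edge_type"])


def ptm_bipartite(
    ptms: Sequence[PTMRecord],
    net: nx.Graph | None = None,
) -> BipartiteNetwork:
    """Directed bipartite network donor → metabolite → receptor.

    When ``net`` is given, only PTMs whose (donor, receptor) pair is an
    edge of that network are kept. Duplicate records collapse to single
    edges; metabolite ids are prefixed so the two node classes never
    collide."""
    kept = []
    for p in ptms:
        if net is not None and not net.has_edge(p.donor, p.receptor):
            continue
        kept.append(p)
    if not kept:
        logger.warning("no transferable metabolites retained; empty network")

    g = nx.DiGraph()
    names: dict[str, str] = {}
    microbes: set[str] = set()
    for p in kept:
        met_node = METABOLITE_NODE_PREFIX + p.metabolite
        g.add_edge(p.donor, met_node)
        g.add_edge(met_node, p.receptor)
        microbes.update((p.donor, p.receptor))
        if p.name and not names.get(met_node):
            names[met_node] = p.name

    rows = [
        {"id": m, "type": "microbe", "name": ""} for m in sorted(microbes)
    ] + [
        {"id": n, "type": "metabolite", "name": names.get(n, "")}
        for n in sorted(v for v in g.nodes if v.startswith(METABOLITE_NODE_PREFIX))
    ]
    node_table = pd.DataFrame(rows, columns=["id", "type", "name"])
    return BipartiteNetwork(graph=g, node_table=node_table)


def heatmap_data(
    matrix: IndexMatrix, order: str = "cluster"
) -> tuple[IndexMatrix, list[str], np.ndarray | None]:
    """Reorder a distance matrix for heatmap display.

    ``cluster`` (default) orders leaves by average-linkage hierarchical
    clustering of the distances; ``input`` keeps the given order. Returns
    (reordered matrix, leaf order, linkage or None). Fewer than 3 rows
    fall back to input order with a notice."""
    if order not in ("cluster", "input"):
        raise ValidationError(f"unknown order {order!r}")
    if not matrix.symmetric:
        raise ValidationError("heatmap needs a symmetric matrix")
    if order == "input" or matrix.n < 3:
        if order == "cluster" and matrix.n < 3:
            logger.info("fewer than 3 rows; using input order")
        return matrix, list(matrix.ids), None
    linkage = average(squareform(matrix.values, checks=False))
    leaf_order = [int(i) for i in leaves_list(linkage)]
    return matrix.reordered(leaf_order), [matrix.ids[i] for i in leaf_order], linkage


def render_heatmap(
    matrix: IndexMatrix, path: str | Path, order: str = "cluster"
) -> Path:
    """Optional figure rendering (headless backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered, leaves, _ = heatmap_data(matrix, order=order)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(ordered.values, cmap="viridis")
    ax.set_xticks(range(ordered.n), labels=leaves, rotation=90, fontsize=7)
    ax.set_yticks(range(ordered.n), labels=leaves, fontsize=7)
    fig.colorbar(im, ax=ax, label=ordered.kind)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(net, path)
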