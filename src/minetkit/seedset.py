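"""Seed-set detection on the directed metabolite graph of a GSMM.

The metabolite graph has an edge from every substrate to every product of
each internal reaction (both directions for reversible reactions). Seed
metabolites are the members of *source* strongly connected components —
components no external metabolite can reach — i.e. compounds the model
cannot synthesise endogenously and must take up from the environment.
Each seed carries a confidence C = 1/(component size); source components
larger than ``max_cc`` are excluded from the seed set and counted as
producible (non-seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import EmptyGraphError, ParameterError, ValidationError
from .gsmm_io import GSMM, normalize_metabolite_id

logger = logging.getLogger(__name__)

DEFAULT_MAX_CC = 5


@dataclass
class MetaboliteGraph:
    """Directed substrate→product graph of one model's metabolites."""

    graph: nx.DiGraph
    origin_model: str

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)


@dataclass
class SCCPartition:
    """Strongly connected components of a metabolite graph."""

    components: list[frozenset[str]]
    component_of: dict[str, int]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for comp in self.components:
            if seen & comp:
                raise ValidationError("SCC components overlap")
            seen |= comp


@dataclass
class SeedSet:
    """Seed metabolites of one model with confidences C = 1/|SCC|."""

    model_id: str
    seeds: dict[str, float]
    nonseeds: set[str]
    all_metabolites: set[str]
    max_cc: int

    def __post_init__(self) -> None:
        if set(self.seeds) & self.nonseeds:
            raise ValidationError("seeds and nonseeds overlap")
        if set(self.seeds) | self.nonseeds != self.all_metabolites:
            raise ValidationError("seeds ∪ nonseeds must cover all metabolites")

    @property
    def seed_ids(self) -> set[str]:
        return set(self.seeds)


def _resolve_rule(rule: str | Callable[[str], str]) -> Callable[[str], str]:
    if callable(rule):
        return rule
    return lambda full_id: normalize_metabolite_id(full_id, rule)


def build_metabolite_graph(
    model: GSMM,
    rule: str | Callable[[str], str] = "strip",
    ignore: Iterable[str] = (),
) -> MetaboliteGraph:
    """Directed graph over (normalized) internal metabolite ids.

    Boundary species and exchange reactions contribute no edges; self-loops
    created by normalization (substrate == product) are dropped. ``ignore``
    is an optional set of base ids (e.g. currency metabolites) removed from
    the graph entirely.
    """
    norm = _resolve_rule(rule)
    ignore = set(ignore)
    internal = set(model.internal_metabolites())

    g = nx.DiGraph()
    for met in internal:
        base = norm(met)
        if base not in ignore:
            g.add_node(base)
    if g.number_of_nodes() == 0:
        raise EmptyGraphError(
            f"model {model.model_id} has no internal metabolites"
        )

    for rxn in model.reactions.values():
        if rxn.is_exchange:
            continue  # boundary transfer: no endogenous-synthesis evidence
        subs = [norm(m) for m in rxn.substrates() if m in internal]
        prods = [norm(m) for m in rxn.products() if m in internal]
        subs = [s for s in subs if s not in ignore]
        prods = [p for p in prods if p not in ignore]
        forward = rxn.upper_bound > 0
        backward = rxn.lower_bound < 0
        for s in subs:
            for p in prods:
                if s == p:
                    continue
                if forward:
                    g.add_edge(s, p)
                if backward:
                    g.add_edge(p, s)
    return MetaboliteGraph(graph=g, origin_model=model.model_id)


def compute_sccs(graph: MetaboliteGraph) -> SCCPartition:
    """Exact strongly connected components (deterministic order)."""
    if graph.graph.number_of_nodes() == 0:
        raise EmptyGraphError("cannot compute SCCs of an empty graph")
    comps = [frozenset(c) for c in nx.strongly_connected_components(graph.graph)]
    comps.sort(key=lambda c: min(c))
    component_of = {node: i for i, comp in enumerate(comps) for node in comp}
    return SCCPartition(components=comps, component_of=component_of)


def detect_seed_set(
    graph: MetaboliteGraph, max_cc: int = DEFAULT_MAX_CC
) -> SeedSet:
    """Seeds = members of source SCCs (no incoming edge from outside the
    component) of size ≤ ``max_cc``, each with confidence 1/size."""
    if max_cc < 1:
        raise ParameterError(f"max_cc must be ≥ 1, got {max_cc}")
    partition = compute_sccs(graph)
    comp_of = partition.component_of

    has_external_in = [False] * len(partition.components)
    for u, v in graph.graph.edges:
        cu, cv = comp_of[u], comp_of[v]
        if cu != cv:
            has_external_in[cv] = True

    seeds: dict[str, float] = {}
    oversized = 0
    for i, comp in enumerate(partition.components):
        if has_external_in[i]:
            continue
        if len(comp) > max_cc:
            oversized += 1
            continue
        confidence = 1.0 / len(comp)
        for node in comp:
            seeds[node] = confidence
    if oversized:
        logger.info(
            "model %s: %d source component(s) larger than max_cc=%d excluded "
            "from the seed set",
            graph.origin_model, oversized, max_cc,
        )
    all_mets = set(graph.graph.nodes)
    return SeedSet(
        model_id=graph.origin_model,
        seeds=seeds,
        nonseeds=all_mets - set(seeds),
        all_metabolites=all_mets,
        max_cc=max_cc,
    )


def brute_force_seed_oracle(
    graph: MetaboliteGraph, max_cc: int = DEFAULT_MAX_CC
) -> SeedSet:
    """Reference implementation via explicit transitive closure.

    A node belongs to a seed component iff no node outside its mutual
    reachability class reaches it, and the class has at most ``max_cc``
    members. Refuses graphs with more than 50 nodes.
    """
    if max_cc < 1:
        raise ParameterError(f"max_cc must be ≥ 1, got {max_cc}")
    nodes = sorted(graph.graph.nodes)
    n = len(nodes)
    if n == 0:
        raise EmptyGraphError("empty graph")
    if n > 50:
        raise ParameterError(f"oracle refuses graphs with >50 nodes (got {n})")
    index = {v: i for i, v in enumerate(nodes)}

    reach = np.eye(n, dtype=bool)
    for u, v in graph.graph.edges:
        reach[index[u], index[v]] = True
    for _ in range(n):  # boolean closure by repeated relaxation
        new = reach | ((reach.astype(np.int16) @ reach.astype(np.int16)) > 0)
        if np.array_equal(new, reach):
            break
        reach = new

    mutual = reach & reach.T
    seeds: dict[str, float] = {}
    for i, node in enumerate(nodes):
        cls = np.flatnonzero(mutual[i])
        outside_reaches = any(
            reach[j, i] for j in range(n) if not mutual[i, j]
        )
        if not outside_reaches and len(cls) <= max_cc:
            seeds[node] = 1.0 / len(cls)
    all_mets = set(nodes)
    return SeedSet(
        model_id=graph.origin_model,
        seeds=seeds,
        nonseeds=all_mets - set(seeds),
        all_metabolites=all_mets,
        max_cc=max_cc,
    )


def seed_set_for_model(
    model: GSMM,
    max_cc: int = DEFAULT_MAX_CC,
    rule: str | Callable[[str], str] = "strip",
    ignore: Iterable[str] = (),
) -> SeedSet:
    """Convenience composition: graph construction + seed detection."""
    return detect_seed_set(build_metabolite_graph(model, rule, ignore), max_cc)


def seed_sets_to_frame(seed_sets: Iterable[SeedSet]) -> pd.DataFrame:
    """Long-form table: model_id, metabolite, confidence, is_seed."""
    rows = []
    for ss in seed_sets:
        for met in sorted(ss.all_metabolites):
            is_seed = met in ss.seeds
            rows.append(
                {
                    "model_id": ss.model_id,
                    "metabolite": met,
                    "confidence": ss.seeds.get(met, 0.0),
                    "is_seed": is_seed,
                }
            )
    return pd.DataFrame(rows, columns=["model_id", "metabolite", "confidence", "is_seed"])


def write_seed_sets(seed_sets: Iterable[SeedSet], path: str | Path) -> None:
    seed_sets_to_frame(seed_sets).to_csv(path, sep="\t", index=False)
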