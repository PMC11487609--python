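"""Flux balance analysis, parsimonious FBA, and flux-based distances.

FBA maximises a linear objective (default the ``Growth`` reaction) over
the steady-state flux polytope S·v = 0, lb ≤ v ≤ ub. pFBA then fixes the
optimal objective flux and minimises Σ|v| by splitting every reaction
into non-negative forward/backward parts. Per-model pFBA flux vectors are
assembled over the union of reactions carrying flux in at least one
model, and pairwise Euclidean (raw and per-reaction standardized)
distances between the vectors serve as metabolic distances.

LPs are solved with scipy's HiGHS interface, which is deterministic for a
fixed model, so repeated runs give identical flux tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial.distance import pdist, squareform

from .errors import FluxError, ObjectiveNotFoundError, ValidationError
from .gsmm_io import GSMM
from .matrix import IndexMatrix

logger = logging.getLogger(__name__)

DEFAULT_OBJECTIVE = "Growth"
STEADY_STATE_TOL = 1e-6


@dataclass
class FBAResult:
    model_id: str
    objective_id: str
    objective_value: float
    fluxes: dict[str, float]
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux_l1(self) -> float:
        return float(sum(abs(v) for v in self.fluxes.values()))


@dataclass
class FluxTable:
    """model × reaction flux matrix over reactions active in ≥1 model."""

    model_ids: list[str]
    reaction_ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.model_ids, columns=self.reaction_ids
        )


@dataclass
class DistanceResult:
    raw: IndexMatrix
    standardized: IndexMatrix
    long_table: pd.DataFrame
    excluded: list[str] = field(default_factory=list)


def _stoichiometric_system(model: GSMM):
    rxn_ids = list(model.reactions)
    internal = model.internal_metabolites()
    met_index = {m: i for i, m in enumerate(internal)}
    S = np.zeros((len(internal), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for met, coef in model.reactions[rid].stoichiometry.items():
            i = met_index.get(met)
            if i is not None:
                S[i, j] = coef
    bounds = [
        (model.reactions[r].lower_bound, model.reactions[r].upper_bound)
        for r in rxn_ids
    ]
    return rxn_ids, S, bounds


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded"}


def _biomass_candidates(model: GSMM) -> list[str]:
    hits = []
    for rid, rxn in model.reactions.items():
        text = f"{rid} {rxn.name}".lower()
        if "growth" in text or "biomass" in text:
            hits.append(rid)
    return hits


def fba(model: GSMM, objective: str = DEFAULT_OBJECTIVE) -> FBAResult:
    """Maximise the flux through ``objective`` at steady state."""
    if objective not in model.reactions:
        raise ObjectiveNotFoundError(
            f"model {model.model_id}: objective reaction {objective!r} not "
            f"found; biomass-like candidates: {_biomass_candidates(model) or 'none'}"
        )
    rxn_ids, S, bounds = _stoichiometric_system(model)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective)] = -1.0  # linprog minimises
    res = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs"
    )
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        logger.warning("model %s: FBA %s", model.model_id, status)
        return FBAResult(model.model_id, objective, float("nan"), {}, status)
    fluxes = {rid: float(v) for rid, v in zip(rxn_ids, res.x)}
    return FBAResult(
        model.model_id, objective, float(-res.fun), fluxes, "optimal"
    )


def pfba(
    model: GSMM,
    objective: str = DEFAULT_OBJECTIVE,
    fix_tolerance: float = 1e-9,
    fraction_of_optimum: float = 1.0,
) -> FBAResult:
    """Minimise Σ|v| with the FBA optimum (× ``fraction_of_optimum``) fixed.

    Every reaction is split into forward/backward non-negative parts so the
    second stage stays a plain LP. On numerical infeasibility the fix
    tolerance is relaxed tenfold once before giving up.
    """
    stage1 = fba(model, objective)
    if not stage1.optimal:
        return stage1
    target = stage1.objective_value * fraction_of_optimum

    rxn_ids, S, bounds = _stoichiometric_system(model)
    n = len(rxn_ids)
    obj_idx = rxn_ids.index(objective)

    # v = p - q with p in [max(lb,0), max(ub,0)], q in [max(-ub,0), max(-lb,0)]
    p_bounds = [(max(lb, 0.0), max(ub, 0.0)) for lb, ub in bounds]
    q_bounds = [(max(-ub, 0.0), max(-lb, 0.0)) for lb, ub in bounds]
    A_eq = np.hstack([S, -S])
    c = np.ones(2 * n)

    tol = fix_tolerance
    for attempt in range(2):
        slack = max(abs(target), 1.0) * tol
        row = np.zeros(2 * n)
        row[obj_idx] = 1.0
        row[n + obj_idx] = -1.0
        A_ub = np.vstack([row, -row])
        b_ub = np.array([target + slack, -(target - slack)])
        res = linprog(
            c,
            A_eq=A_eq,
            b_eq=np.zeros(A_eq.shape[0]),
            A_ub=A_ub,
            b_ub=b_ub,
            bounds=p_bounds + q_bounds,
            method="highs",
        )
        if res.status == 0:
            v = res.x[:n] - res.x[n:]
            fluxes = {rid: float(x) for rid, x in zip(rxn_ids, v)}
            return FBAResult(
                model.model_id, objective, float(v[obj_idx]), fluxes, "optimal"
            )
        tol *= 10
        logger.warning(
            "model %s: pFBA stage 2 %s, retrying with fix tolerance %g",
            model.model_id, _STATUS.get(res.status, "failed"), tol,
        )
    raise FluxError(
        f"model {model.model_id}: pFBA stage 2 infeasible even at relaxed "
        f"tolerance {tol:g}"
    )


def build_flux_table(
    results: Sequence[FBAResult], zero_threshold: float = 1e-9
) -> FluxTable:
    """Union of reactions with |flux| > threshold in ≥1 model; absent
    reactions are filled with 0."""
    usable = [r for r in results if r.optimal]
    if len(usable) < 2:
        raise FluxError(
            f"need ≥2 models with optimal flux solutions, got {len(usable)}"
        )
    active: set[str] = set()
    for r in usable:
        active |= {rid for rid, v in r.fluxes.items() if abs(v) > zero_threshold}
    reaction_ids = sorted(active)
    values = np.zeros((len(usable), len(reaction_ids)))
    for i, r in enumerate(usable):
        for j, rid in enumerate(reaction_ids):
            values[i, j] = r.fluxes.get(rid, 0.0)
    return FluxTable(
        model_ids=[r.model_id for r in usable],
        reaction_ids=reaction_ids,
        values=values,
    )


def euclidean_distances(table: FluxTable) -> IndexMatrix:
    """Pairwise Euclidean distances between model flux vectors."""
    d = squareform(pdist(table.values, metric="euclidean"))
    return IndexMatrix(
        ids=list(table.model_ids), values=d, symmetric=True, kind="distance"
    )


def standardized_distances(table: FluxTable) -> IndexMatrix:
    """Euclidean distances after per-reaction standardization across models
    (sample sd, n−1); zero-variance reaction columns are dropped."""
    if len(table.model_ids) < 2:
        raise FluxError("need ≥2 models to standardize")
    sd = table.values.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = int((~keep).sum())
    if not keep.any():
        raise FluxError(
            "all reaction columns have zero variance: models are "
            "metabolically identical"
        )
    if dropped:
        logger.info("standardization dropped %d zero-variance column(s)", dropped)
    vals = table.values[:, keep]
    z = (vals - vals.mean(axis=0)) / sd[keep]
    d = squareform(pdist(z, metric="euclidean"))
    return IndexMatrix(
        ids=list(table.model_ids), values=d, symmetric=True, kind="distance"
    )


def distance_long_table(matrix: IndexMatrix) -> pd.DataFrame:
    """Three-column table (model A, model B, distance), lexicographic pairs."""
    order = np.argsort(matrix.ids)
    sorted_mat = matrix.reordered(list(order))
    rows = [
        {"model_A": a, "model_B": b, "euclidean_distance": v}
        for a, b, v in sorted_mat.pair_records()
    ]
    return pd.DataFrame(rows, columns=["model_A", "model_B", "euclidean_distance"])


def metabolic_distance(
    models: Sequence[GSMM],
    objective: str = DEFAULT_OBJECTIVE,
    zero_threshold: float = 1e-9,
) -> DistanceResult:
    """pFBA every model and derive raw/standardized distance matrices plus
    the long pair table. Models whose objective is missing or whose LP is
    not optimal are excluded (logged), not fatal."""
    results: list[FBAResult] = []
    excluded: list[str] = []
    for model in models:
        try:
            res = pfba(model, objective)
        except (ObjectiveNotFoundError, FluxError) as exc:
            logger.warning("excluding %s from distances: %s", model.model_id, exc)
            excluded.append(model.model_id)
            continue
        if res.optimal:
            results.append(res)
        else:
            logger.warning(
                "excluding %s from distances: FBA status %s",
                model.model_id, res.status,
            )
            excluded.append(model.model_id)
    table = build_flux_table(results, zero_threshold)
    raw = euclidean_distances(table)
    std = standardized_distances(table)
    return DistanceResult(
        raw=raw,
        standardized=std,
        long_table=distance_long_table(raw),
        excluded=excluded,
    )
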