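"""Pairwise competition/complementarity indices and transferable metabolites.

Given per-model seed sets, the competition index of an ordered pair (A, B)
is the confidence-weighted fraction of A's seeds that are also seeds of B;
the complementarity index is the unweighted fraction of A's seeds, among
those present in B at all, that B can produce (B's non-seeds). A
"potentially transferable metabolite" (PTM) for receptor A and donor B is
any member of seeds(A) ∩ nonseeds(B) — exactly the complementarity
numerator.

Both indices are asymmetric and lie in [0, 1]. Degenerate cases (empty
seed set of A, or A's seeds sharing no metabolite with B) return 0 with a
logged warning so matrices stay total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CompletenessError, ValidationError
from .matrix import IndexMatrix
from .seedset import SeedSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionRecord:
    """One ordered model pair with both indices (focal model = ``a``)."""

    a: str
    b: str
    mi_competition: float
    mi_complementarity: float


@dataclass(frozen=True)
class PTMRecord:
    """A metabolite the receptor needs (seed) and the donor can make
    (non-seed)."""

    donor: str
    receptor: str
    metabolite: str
    name: str = ""


def mi_competition(seed_a: SeedSet, seed_b: SeedSet) -> float:
    """Σ C over seeds(A) ∩ seeds(B), divided by Σ C over seeds(A)."""
    total = sum(seed_a.seeds.values())
    if total == 0:
        logger.warning(
            "model %s has an empty seed set; competition index defined as 0",
            seed_a.model_id,
        )
        return 0.0
    shared = sum(
        c for met, c in seed_a.seeds.items() if met in seed_b.seeds
    )
    return shared / total


def mi_complementarity(seed_a: SeedSet, seed_b: SeedSet) -> float:
    """|seeds(A) ∩ nonseeds(B)| / |seeds(A) ∩ metabolites(B)|.

    Counts are unweighted cardinalities; a zero denominator (A's seeds
    share no metabolite with B) yields 0 with a warning.
    """
    seeds_a = seed_a.seed_ids
    numerator = len(seeds_a & seed_b.nonseeds)
    denominator = len(seeds_a & seed_b.all_metabolites)
    if denominator == 0:
        logger.warning(
            "models %s/%s share no seed metabolite of %s; complementarity "
            "index defined as 0",
            seed_a.model_id, seed_b.model_id, seed_a.model_id,
        )
        return 0.0
    return numerator / denominator


def complementarity_numerator(seed_a: SeedSet, seed_b: SeedSet) -> int:
    """|seeds(A) ∩ nonseeds(B)| — equals the PTM count for (A ← B)."""
    return len(seed_a.seed_ids & seed_b.nonseeds)


def all_pairwise(seedsets: Sequence[SeedSet]) -> list[InteractionRecord]:
    """Both indices for every ordered pair including self-pairs (n² rows,
    lexicographic order)."""
    if len(seedsets) < 2:
        raise ValidationError("need at least 2 models for pairwise indices")
    ids = [ss.model_id for ss in seedsets]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate model ids: {sorted(ids)}")
    by_id = {ss.model_id: ss for ss in seedsets}
    records = []
    for a in sorted(by_id):
        for b in sorted(by_id):
            records.append(
                InteractionRecord(
                    a=a,
                    b=b,
                    mi_competition=mi_competition(by_id[a], by_id[b]),
                    mi_complementarity=mi_complementarity(by_id[a], by_id[b]),
                )
            )
    return records


def find_ptms(
    seedsets: Sequence[SeedSet],
    names: Mapping[str, str] | None = None,
) -> list[PTMRecord]:
    """PTMs for every ordered (receptor, donor) pair of distinct models."""
    if len(seedsets) < 2:
        raise ValidationError("need at least 2 models for PTM detection")
    names = names or {}
    by_id = {ss.model_id: ss for ss in seedsets}
    out = []
    for receptor in sorted(by_id):
        for donor in sorted(by_id):
            if donor == receptor:
                continue
            shared = by_id[receptor].seed_ids & by_id[donor].nonseeds
            for met in sorted(shared):
                out.append(
                    PTMRecord(
                        donor=donor,
                        receptor=receptor,
                        metabolite=met,
                        name=names.get(met, ""),
                    )
                )
    return out


def to_matrix(
    records: Iterable[InteractionRecord],
    index: str,
    mode: str = "max_symmetric",
) -> IndexMatrix:
    """Shape the ordered-pair record table into a square matrix.

    ``max_symmetric`` (default) keeps the larger of the two directed values
    per unordered pair; ``asymmetric`` keeps the original directed values.
    The diagonal is 0 in both modes.
    """
    if index not in ("competition", "complementarity"):
        raise ValidationError(f"unknown index {index!r}")
    if mode not in ("max_symmetric", "asymmetric"):
        raise ValidationError(f"unknown mode {mode!r}")
    values = {}
    for rec in records:
        values[(rec.a, rec.b)] = getattr(rec, f"mi_{index}")
    ids = sorted({a for a, _ in values} | {b for _, b in values})
    n = len(ids)
    mat = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i == j:
                continue
            if (a, b) not in values or (b, a) not in values:
                raise CompletenessError(f"record table misses pair ({a}, {b})")
            if mode == "max_symmetric":
                mat[i, j] = max(values[(a, b)], values[(b, a)])
            else:
                mat[i, j] = values[(a, b)]
    return IndexMatrix(
        ids=ids, values=mat, symmetric=(mode == "max_symmetric"), kind=index
    )


def records_to_frame(records: Iterable[InteractionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "A": r.a,
                "B": r.b,
                "MI_competition": r.mi_competition,
                "MI_complementarity": r.mi_complementarity,
            }
            for r in records
        ],
        columns=["A", "B", "MI_competition", "MI_complementarity"],
    )


def frame_to_records(df: pd.DataFrame) -> list[InteractionRecord]:
    return [
        InteractionRecord(
            a=str(row["A"]),
            b=str(row["B"]),
            mi_competition=float(row["MI_competition"]),
            mi_complementarity=float(row["MI_complementarity"]),
        )
        for _, row in df.iterrows()
    ]


def ptms_to_frame(ptms: Iterable[PTMRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "donor": p.donor,
                "receptor": p.receptor,
                "metabolite": p.metabolite,
                "name": p.name,
            }
            for p in ptms
        ],
        columns=["donor", "receptor", "metabolite", "name"],
    )


def frame_to_ptms(df: pd.DataFrame) -> list[PTMRecord]:
    return [
        PTMRecord(
            donor=str(row["donor"]),
            receptor=str(row["receptor"]),
            metabolite=str(row["metabolite"]),
            name="" if pd.isna(row.get("name", "")) else str(row.get("name", "")),
        )
        for _, row in df.iterrows()
    ]
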