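"""Labeled square matrices passed between pipeline stages.

An :class:`IndexMatrix` carries an ordered list of node/model identifiers,
a square array of pairwise values, a symmetry flag, and a ``kind`` tag that
downstream stages use to pick sensible defaults (e.g. a ``distance`` matrix
must be converted to a similarity before RMT thresholding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

KINDS = ("complementarity", "competition", "distance", "similarity", "generic")


@dataclass
class IndexMatrix:
    """Square labeled matrix of pairwise interaction values.

    The diagonal is forced to zero on construction (networks carry no
    self-edges). When ``symmetric`` is set the array must equal its
    transpose exactly.
    """

    ids: list[str]
    values: np.ndarray
    symmetric: bool
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float).copy()
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise ValidationError("duplicate ids in matrix")
        if self.kind not in KINDS:
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        np.fill_diagonal(self.values, 0.0)
        if self.symmetric and not np.array_equal(self.values, self.values.T):
            raise ValidationError("symmetric flag set but matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle (i<j) values as a flat array."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def pair_records(self) -> list[tuple[str, str, float]]:
        """(id_i, id_j, value) for every unordered pair i<j."""
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                out.append((self.ids[i], self.ids[j], float(self.values[i, j])))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        kind: str = "generic",
        symmetric: bool | None = None,
    ) -> "IndexMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.map(str)
        df.columns = df.columns.map(str)
        if list(df.index) != list(df.columns):
            raise ValidationError(f"{path}: row and column labels differ")
        values = df.to_numpy(dtype=float)
        if symmetric is None:
            symmetric = bool(np.array_equal(values, values.T))
        return cls(ids=list(df.index), values=values, symmetric=symmetric, kind=kind)

    def reordered(self, order: Sequence[int]) -> "IndexMatrix":
        """Symmetric permutation of rows/columns by positional index."""
        order = list(order)
        if sorted(order) != list(range(self.n)):
            raise ValidationError("order must be a permutation of matrix indices")
        idx = np.asarray(order)
        return IndexMatrix(
            ids=[self.ids[i] for i in order],
            values=self.values[np.ix_(idx, idx)],
            symmetric=self.symmetric,
            kind=self.kind,
        )
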