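"""Network threshold selection: RMT spacing tests and Z-score outliers.

The RMT scan thresholds a symmetric [0,1] matrix over a grid of cutoffs
and, at each cutoff, tests whether the nearest-neighbour spacing
distribution (NNSD) of the unfolded eigenvalues is consistent with
Poisson statistics P(s) = e^(−s). Correlated (signal-dominated) matrices
follow GOE-like statistics; as the cutoff removes noise the NNSD
transitions to Poisson. The chosen cutoff is the smallest grid value at
which Poisson consistency (p ≥ alpha) holds and persists for the next two
grid steps.

The Z-score route flags outlying pairwise values directly, using either
the standard score (mean/sd) or the modified score based on the median
and the median absolute deviation with the 0.6745 normal-consistency
constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .errors import (
    DegenerateScaleError,
    InsufficientSpectrumError,
    NormalizationError,
    ParameterError,
    ThresholdError,
    ValidationError,
)
from .matrix import IndexMatrix

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_ZSCORE_CUTOFF = 2.698
ALTERNATIVE_ZSCORE_CUTOFF = 3.5
MODIFIED_Z_CONSTANT = 0.6745
EIGENVALUE_DEDUP_TOL = 1e-8
MIN_SPECTRUM_SIZE = 10
STABILITY_STEPS = 2


@dataclass
class ThresholdScanResult:
    test: str
    alpha: float
    thresholds: list[float]
    n_nodes_kept: list[int]
    n_edges_kept: list[int]
    statistics: list[float]
    p_values: list[float]
    chosen_threshold: float | None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "threshold": self.thresholds,
                "n_nodes": self.n_nodes_kept,
                "n_edges": self.n_edges_kept,
                "statistic": self.statistics,
                "p_value": self.p_values,
            }
        )
        df["chosen"] = [
            self.chosen_threshold is not None and t == self.chosen_threshold
            for t in self.thresholds
        ]
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class OutlierResult:
    method: str
    cutoff: float
    records: pd.DataFrame  # columns A, B, value, z, flagged
    center: float
    scale: float
    implied_value_threshold: float | None

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def unfold_eigenvalues(eigenvalues: Sequence[float]) -> np.ndarray:
    """Map a sorted spectrum to unit mean spacing.

    Duplicates (within 1e-8) are collapsed first; the cumulative spectral
    count is approximated by a strictly increasing monotone cubic through
    ~max(5, n/10) quantile knots, and each eigenvalue is mapped to
    n·F(λ).
    """
    evs = np.sort(np.asarray(eigenvalues, dtype=float))
    if evs.size:
        keep = [evs[0]]
        for e in evs[1:]:
            if e - keep[-1] > EIGENVALUE_DEDUP_TOL:
                keep.append(e)
        evs = np.asarray(keep)
    n = evs.size
    if n < MIN_SPECTRUM_SIZE:
        raise InsufficientSpectrumError(
            f"need ≥{MIN_SPECTRUM_SIZE} distinct eigenvalues, got {n}"
        )
    n_knots = max(5, n // 10)
    probs = np.linspace(0.0, 1.0, n_knots)
    knots_x = np.quantile(evs, probs)
    knots_x, idx = np.unique(knots_x, return_index=True)
    knots_y = probs[idx]
    if knots_x.size < 2:
        raise InsufficientSpectrumError("degenerate spectrum: all knots equal")
    cdf = PchipInterpolator(knots_x, knots_y)
    return n * np.asarray(cdf(evs))


def nearest_neighbour_spacings(unfolded: Sequence[float]) -> np.ndarray:
    u = np.sort(np.asarray(unfolded, dtype=float))
    if u.size < 2:
        raise InsufficientSpectrumError("need ≥2 unfolded eigenvalues")
    return np.diff(u)


def poisson_spacing_test(spacings: Sequence[float], test: str = "chisq") -> float:
    """p-value of the spacing sample against the Poisson NNSD Exp(1).

    chisq: Pearson test over ⌈√n⌉ equal-probability Exp(1) bins
    (df = bins − 1). ks: one-sample Kolmogorov–Smirnov against
    F(s) = 1 − e^(−s).
    """
    s = np.asarray(spacings, dtype=float)
    if s.size == 0:
        raise ValidationError("empty spacing sample")
    if test == "ks":
        return float(stats.kstest(s, "expon").pvalue)
    if test != "chisq":
        raise ParameterError(f"unknown test {test!r}")
    k = int(np.ceil(np.sqrt(s.size)))
    k = max(k, 2)
    edges = np.append(-np.log(1.0 - np.arange(k) / k), np.inf)
    observed, _ = np.histogram(s, bins=edges)
    expected = np.full(k, s.size / k)
    statistic = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(statistic, df=k - 1))


def _validate_rmt_input(matrix: IndexMatrix) -> np.ndarray:
    if not matrix.symmetric or not np.array_equal(matrix.values, matrix.values.T):
        raise ValidationError(
            "RMT scan needs a symmetric matrix; use max-symmetrization "
            "(to_matrix mode='max_symmetric') first"
        )
    vals = matrix.values
    off = matrix.off_diagonal()
    if off.size and (off.min() < 0 or off.max() > 1):
        raise NormalizationError(
            "matrix values must lie in [0, 1]; for distance matrices apply "
            "distance_to_similarity first"
        )
    return vals


def _threshold_spectrum(values: np.ndarray, t: float):
    a = values.copy()
    a[a < t] = 0.0
    np.fill_diagonal(a, 0.0)
    degree = (a > 0).sum(axis=1)
    keep = degree > 0
    a = a[np.ix_(keep, keep)]
    n_nodes = int(keep.sum())
    n_edges = int((a > 0).sum() // 2)
    return a, n_nodes, n_edges


def rmt_scan(
    matrix: IndexMatrix,
    test: str = "chisq",
    t_min: float = 0.01,
    t_max: float = 0.99,
    step: float = 0.01,
    alpha: float = DEFAULT_ALPHA,
) -> ThresholdScanResult:
    """Scan candidate cutoffs and pick the Poisson-transition threshold.

    At each cutoff entries below it are zeroed, isolated nodes dropped and
    the NNSD of the remaining weighted spectrum tested against Exp(1). The
    chosen threshold is the smallest cutoff whose p-value is ≥ alpha and
    stays ≥ alpha for the next two grid steps; the scan stops once fewer
    than 10 nodes (or distinct eigenvalues) remain.
    """
    if test not in ("chisq", "ks"):
        raise ParameterError(f"unknown test {test!r}")
    values = _validate_rmt_input(matrix)
    grid = np.round(np.arange(t_min, t_max + step / 2, step), 10)

    thresholds, nodes_kept, edges_kept, statistics, p_values = [], [], [], [], []
    for t in grid:
        a, n_nodes, n_edges = _threshold_spectrum(values, float(t))
        if n_nodes < MIN_SPECTRUM_SIZE:
            logger.info("scan stopped at %.4f: %d nodes remain", t, n_nodes)
            break
        try:
            eigenvalues = np.linalg.eigvalsh(a)
            spacings = nearest_neighbour_spacings(unfold_eigenvalues(eigenvalues))
            p = poisson_spacing_test(spacings, test)
            statistic = float(stats.kstest(spacings, "expon").statistic)
        except InsufficientSpectrumError:
            logger.info("scan stopped at %.4f: spectrum too small", t)
            break
        thresholds.append(float(t))
        nodes_kept.append(n_nodes)
        edges_kept.append(n_edges)
        statistics.append(statistic)
        p_values.append(float(p))

    chosen = None
    for i, p in enumerate(p_values):
        if p < alpha:
            continue
        window = p_values[i + 1 : i + 1 + STABILITY_STEPS]
        if len(window) == STABILITY_STEPS and all(q >= alpha for q in window):
            chosen = thresholds[i]
            break
    if chosen is None:
        logger.warning("no threshold satisfied the RMT criterion (alpha=%g)", alpha)
    return ThresholdScanResult(
        test=test,
        alpha=alpha,
        thresholds=thresholds,
        n_nodes_kept=nodes_kept,
        n_edges_kept=edges_kept,
        statistics=statistics,
        p_values=p_values,
        chosen_threshold=chosen,
    )


def _outlier_values(matrix: IndexMatrix | Sequence[float]):
    if isinstance(matrix, IndexMatrix):
        if not matrix.symmetric:
            raise ValidationError("outlier detection needs a symmetric matrix")
        labels = matrix.pair_records()
        values = np.array([v for _, _, v in labels])
        pairs = [(a, b) for a, b, _ in labels]
    else:
        values = np.asarray(list(matrix), dtype=float)
        pairs = [(str(i), "") for i in range(values.size)]
    return pairs, values


def zscore_outliers(
    matrix: IndexMatrix | Sequence[float],
    method: str = "modified",
    cutoff: float = DEFAULT_ZSCORE_CUTOFF,
) -> OutlierResult:
    """Flag pairwise values with |Z| > cutoff.

    standard: Z = (x − mean)/sd (sample sd, n−1).
    modified: Z = 0.6745·(x − median)/MAD.
    """
    if method not in ("standard", "modified"):
        raise ParameterError(f"unknown method {method!r}")
    pairs, values = _outlier_values(matrix)
    if values.size < 5:
        raise ValidationError(f"need ≥5 values for outlier detection, got {values.size}")
    if method == "standard":
        center = float(values.mean())
        scale = float(values.std(ddof=1))
        if scale == 0:
            raise DegenerateScaleError("standard deviation is zero")
        z = (values - center) / scale
    else:
        center = float(np.median(values))
        scale = float(np.median(np.abs(values - center)))
        if scale == 0:
            raise DegenerateScaleError(
                "MAD is zero; consider the standard method"
            )
        z = MODIFIED_Z_CONSTANT * (values - center) / scale
    flagged = np.abs(z) > cutoff
    implied = float(np.abs(values[flagged]).min()) if flagged.any() else None
    records = pd.DataFrame(
        {
            "A": [a for a, _ in pairs],
            "B": [b for _, b in pairs],
            "value": values,
            "z": z,
            "flagged": flagged,
        }
    )
    return OutlierResult(
        method=method,
        cutoff=cutoff,
        records=records,
        center=center,
        scale=scale,
        implied_value_threshold=implied,
    )


def distance_to_similarity(matrix: IndexMatrix) -> IndexMatrix:
    """Affine inversion of a distance matrix onto [0, 1]:
    s = 1 − (d − min)/(max − min) over off-diagonal entries."""
    if not matrix.symmetric:
        raise ValidationError("need a symmetric distance matrix")
    off = matrix.off_diagonal()
    if off.size == 0:
        raise ValidationError("matrix has no off-diagonal entries")
    if off.min() < 0:
        raise ValidationError("distances must be non-negative")
    lo, hi = float(off.min()), float(off.max())
    if hi == lo:
        raise NormalizationError("all distances equal; cannot rescale")
    sim = 1.0 - (matrix.values - lo) / (hi - lo)
    np.fill_diagonal(sim, 0.0)
    return IndexMatrix(
        ids=list(matrix.ids), values=sim, symmetric=True, kind="similarity"
    )


def apply_threshold(
    matrix: IndexMatrix,
    threshold: float,
    direction: str = "ge",
    weighted: bool = False,
) -> nx.Graph:
    """Build the final network: edge iff value ≥ threshold (``ge``) or
    ≤ threshold (``le``, for distance matrices). Isolated nodes are
    dropped (logged); a threshold keeping zero edges is an error."""
    if direction not in ("ge", "le"):
        raise ParameterError(f"unknown direction {direction!r}")
    if not matrix.symmetric:
        raise ValidationError("network construction needs a symmetric matrix")
    g = nx.Graph()
    g.add_nodes_from(matrix.ids)
    for a, b, v in matrix.pair_records():
        hit = v >= threshold if direction == "ge" else v <= threshold
        if hit:
            if weighted:
                g.add_edge(a, b, weight=v)
            else:
                g.add_edge(a, b)
    if g.number_of_edges() == 0:
        raise ThresholdError(
            f"threshold {threshold} ({direction}) retains zero edges"
        )
    isolated = [n for n, d in g.degree() if d == 0]
    if isolated:
        logger.info("dropping %d isolated node(s): %s", len(isolated), isolated)
        g.remove_nodes_from(isolated)
    g.graph["threshold"] = threshold
    g.graph["direction"] = direction
    g.graph["source_kind"] = matrix.kind
    return g
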