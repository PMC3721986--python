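"""Pearson correlation matrices and thresholded coexpression graphs.

Correlations are computed on natural-scale normalised intensities, all
probe pairs at once (optionally in row blocks for memory; the block size
never changes the result).  Graphs keep only pairs whose correlation
meets a positive threshold ``r_min`` — negative correlations never form
edges — and a mean-correlation matrix across datasets supports the
meta-network analysis in which only relationships conserved across
cohorts survive thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CorrelationMatrix",
    "CorrelationGraph",
    "pearson_correlation",
    "correlation_matrix",
    "build_graph",
    "select_threshold",
    "default_threshold_grid",
    "mean_pearson",
]


@dataclass
class CorrelationMatrix:
    """Symmetric all-pairs Pearson matrix over probe identifiers.

    Entries involving a zero-variance probe are NaN ("undefined"); they
    never give rise to graph edges.  The diagonal is defined as 1.
    """

    ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.ids)
        if self.r.shape != (n, n):
            raise ValueError(f"r has shape {self.r.shape}, expected ({n}, {n})")
        if len(set(self.ids)) != n:
            raise ValueError("correlation matrix ids must be unique")
        finite = np.isfinite(self.r)
        if np.any(np.abs(self.r[finite]) > 1 + 1e-12):
            raise ValueError("|r| exceeds 1 beyond numerical tolerance")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class CorrelationGraph:
    """Weighted undirected graph of probe pairs with r >= r_min.

    ``edges`` maps each unordered pair (stored once, smaller identifier
    first) to its correlation weight.  Probes that fail to gain a single
    edge at the threshold are kept in ``isolated`` so node-inclusion
    statistics can be computed.
    """

    edges: dict[tuple[str, str], float]
    isolated: list[str]
    r_min: float

    def __post_init__(self) -> None:
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if b < a:
                raise ValueError(f"edge ({a!r}, {b!r}) not stored in canonical order")
            if w < self.r_min - 1e-12:
                raise ValueError(f"edge ({a}, {b}) weight {w} below r_min {self.r_min}")

    @property
    def nodes(self) -> list[str]:
        """Connected nodes (>= 1 edge), in sorted order."""
        seen: set[str] = set()
        for a, b in self.edges:
            seen.add(a)
            seen.add(b)
        return sorted(seen)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_triples(self) -> list[tuple[str, str, float]]:
        return [(a, b, w) for (a, b), w in sorted(self.edges.items())]

    def neighbours(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {}
        for a, b in self.edges:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return adj


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors.

    Returns NaN (the "undefined" sentinel, treated as no edge downstream)
    if either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise ValueError("vectors must be 1-D with at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(np.dot(dx, dx))
    sy = np.sqrt(np.dot(dy, dy))
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = float(np.dot(dx, dy) / (sx * sy))
    return max(-1.0, min(1.0, r))


def correlation_matrix(matrix, block_size: int = 2048) -> CorrelationMatrix:
    """All-pairs Pearson correlations over the rows of an expression matrix.

    Rows are standardised once; the Gram matrix is then accumulated in
    row blocks of ``block_size`` so memory stays bounded for large probe
    counts.  Results are independent of the block size.
    """
    values = np.asarray(matrix.values, dtype=float)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    centred = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", centred, centred))
    constant = norms == 0.0
    safe = np.where(constant, 1.0, norms)
    z = centred / safe[:, None]
    n = z.shape[0]
    r = np.empty((n, n), dtype=float)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        r[start:stop] = z[start:stop] @ z.T
    np.clip(r, -1.0, 1.0, out=r)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(ids=list(matrix.row_ids), r=r)


def build_graph(c: CorrelationMatrix, r_min: float) -> CorrelationGraph:
    """Threshold a correlation matrix into a coexpression graph.

    An edge is created for every probe pair with a defined correlation
    ``r >= r_min``; ``r_min`` must be positive, so anti-correlated pairs
    never connect.
    """
    if not r_min > 0:
        raise ValueError("r_min must be positive")
    ids = c.ids
    mask = np.triu(c.r >= r_min, k=1)
    mask &= np.isfinite(np.triu(c.r, k=1))
    ii, jj = np.nonzero(mask)
    edges: dict[tuple[str, str], float] = {}
    connected: set[str] = set()
    for i, j in zip(ii.tolist(), jj.tolist()):
        a, b = ids[i], ids[j]
        if b < a:
            a, b = b, a
        edges[(a, b)] = float(c.r[i, j])
        connected.add(ids[i])
        connected.add(ids[j])
    isolated = sorted(set(ids) - connected)
    return CorrelationGraph(edges=edges, isolated=isolated, r_min=float(r_min))


def default_threshold_grid() -> np.ndarray:
    """Threshold grid 0.60-0.95 in steps of 0.01."""
    return np.round(np.arange(0.60, 0.95 + 1e-9, 0.01), 2)


def included_fraction(c: CorrelationMatrix, r_min: float) -> float:
    """Fraction of probes that appear as connected nodes at ``r_min``."""
    max_r = _max_offdiagonal(c)
    return float(np.mean(max_r >= r_min))


def _max_offdiagonal(c: CorrelationMatrix) -> np.ndarray:
    r = c.r.copy()
    np.fill_diagonal(r, -np.inf)
    r[~np.isfinite(r)] = -np.inf
    return r.max(axis=1)


def select_threshold(
    c: CorrelationMatrix,
    target_fraction: float = 0.40,
    grid: Sequence[float] | None = None,
) -> float:
    """Pick the grid threshold whose node-inclusion is closest to target.

    The inclusion fraction at a threshold is the share of probes with at
    least one edge.  Graph construction aims to retain approximately 40%
    of the probes by default.  Ties are broken toward the lower threshold
    (retaining more data).
    """
    if c.n == 0:
        raise ValueError("empty correlation matrix")
    if grid is None:
        grid = default_threshold_grid()
    grid = sorted(float(t) for t in grid)
    if not grid or grid[0] <= 0 or grid[-1] >= 1:
        raise ValueError("grid thresholds must lie in (0, 1)")
    max_r = _max_offdiagonal(c)
    best_t = grid[0]
    best_dev = float("inf")
    for t in grid:
        frac = float(np.mean(max_r >= t))
        dev = abs(frac - target_fraction)
        if dev < best_dev - 1e-15:
            best_dev = dev
            best_t = t
    return best_t


def mean_pearson(cs: Sequence[CorrelationMatrix]) -> CorrelationMatrix:
    """Entrywise mean correlation across datasets over identical ids.

    A pair that is undefined (NaN) in any single dataset stays undefined
    in the mean.
    """
    if not cs:
        raise ValueError("need at least one correlation matrix")
    ids = cs[0].ids
    for c in cs[1:]:
        if c.ids != ids:
            raise ValueError(
                "correlation matrices must share an identical id list; "
                "intersect probesets upstream"
            )
    stacked = np.stack([c.r for c in cs], axis=0)
    mean_r = stacked.mean(axis=0)
    np.clip(mean_r, -1.0, 1.0, out=mean_r)  # NaN passes through unchanged
    np.fill_diagonal(mean_r, 1.0)
    return CorrelationMatrix(ids=list(ids), r=mean_r)
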