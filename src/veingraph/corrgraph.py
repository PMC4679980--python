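"""Sparse voxelwise correlation graph construction.

All-pairs Pearson correlations are computed tile-by-tile so the dense
N×N matrix is never materialized (for a whole-brain EPI grid it would
run to hundreds of gigabytes). Edges connect voxel pairs whose
correlation magnitude reaches a threshold; the threshold itself is
chosen by a descending scan (start 1.0, step 0.01) stopping at the
largest value whose graph satisfies the sparsity criterion

    S = log(E) / log(K) < s_max,        K = 2E / N,

with E the edge count, N the node count and K the average degree. The
criterion (default bound 4) keeps only the strongest correlations —
in resting-state data predominantly coherent venous signals — while
the subtler parenchymal network correlations stay below threshold.

Thresholding is applied to |r| so that sign-inverted coherent signals
(e.g. opposite-phase venous branches) also form edges; the signed r is
stored as the edge weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Iterator

import numpy as np
import pandas as pd

from .imageio import VoxelIndexMap
from .preprocess import VoxelTimeSeriesMatrix

__all__ = [
    "SparsitySummary",
    "SparseCorrelationGraph",
    "ThresholdScan",
    "sparsity_summary",
    "pearson_edges",
    "build_graph",
    "select_threshold",
    "ThresholdScanError",
]

#: tolerance making |r| >= t inclusive under floating-point rounding, so
#: e.g. identical columns (r = 1 up to rounding) pass the t = 1.00 step
THRESHOLD_TOL = 1e-9

DEFAULT_TILE_SIZE = 1024


class ThresholdScanError(RuntimeError):
    """No threshold in the scan produced a graph meeting the sparsity criterion."""

    def __init__(self, message: str, scan: pd.DataFrame | None = None):
        super().__init__(message)
        self.scan = scan


@dataclass(frozen=True)
class SparsitySummary:
    """Edge-count summary of a thresholded graph and its sparsity statistic."""

    n_nodes: int
    n_edges: int

    @property
    def avg_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes

    @property
    def s_defined(self) -> bool:
        """S requires at least one edge and an average degree above 1."""
        return self.n_edges >= 1 and self.avg_degree > 1.0

    @property
    def s_value(self) -> float | None:
        if not self.s_defined:
            return None
        return log(self.n_edges) / log(self.avg_degree)


def sparsity_summary(n_nodes: int, n_edges: int) -> SparsitySummary:
    """S = log(E)/log(K); flagged undefined (``s_value is None``) when E = 0 or K <= 1."""
    if n_nodes < 1:
        raise ValueError("need at least one node")
    if n_edges < 0:
        raise ValueError("edge count cannot be negative")
    return SparsitySummary(n_nodes=int(n_nodes), n_edges=int(n_edges))


@dataclass
class SparseCorrelationGraph:
    """Thresholded correlation graph: in-mask voxels as nodes, signed r as weights."""

    n_nodes: int
    edges_i: np.ndarray  # int, i < j
    edges_j: np.ndarray
    edges_r: np.ndarray  # signed Pearson r, |r| >= threshold
    threshold: float
    index_map: VoxelIndexMap | None = None

    def __post_init__(self) -> None:
        self.edges_i = np.asarray(self.edges_i, dtype=np.intp)
        self.edges_j = np.asarray(self.edges_j, dtype=np.intp)
        self.edges_r = np.asarray(self.edges_r, dtype=np.float64)
        if not (len(self.edges_i) == len(self.edges_j) == len(self.edges_r)):
            raise ValueError("edge arrays must have equal length")

    @property
    def n_edges(self) -> int:
        return len(self.edges_r)

    @property
    def summary(self) -> SparsitySummary:
        return sparsity_summary(self.n_nodes, self.n_edges)

    def edge_set(self) -> set[tuple[int, int]]:
        return set(zip(self.edges_i.tolist(), self.edges_j.tolist()))

    def to_edge_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"i": self.edges_i, "j": self.edges_j, "r": self.edges_r})

    def write_edge_list(self, path) -> None:
        """Whitespace-separated ``i j r`` text export with a one-line header."""
        with open(path, "w") as fh:
            fh.write("i j r\n")
            for i, j, r in zip(self.edges_i, self.edges_j, self.edges_r):
                fh.write(f"{i} {j} {r:.10g}\n")


@dataclass
class ThresholdScan:
    """Result of the descending threshold scan."""

    threshold: float
    summary: SparsitySummary
    table: pd.DataFrame  # columns: threshold, n_edges, avg_degree, s

    def __iter__(self):  # allow (threshold, summary) unpacking
        return iter((self.threshold, self.summary))


def _standardized_columns(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale columns to unit norm; zero-variance columns become all-zero.

    With columns z_i = (x_i - mean) / ||x_i - mean||, the Pearson
    coefficient is the plain dot product z_i . z_j.
    """
    values = np.asarray(values, dtype=np.float64)
    centered = values - values.mean(axis=0, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=0))
    valid = norms > 0
    safe = np.where(valid, norms, 1.0)
    z = centered / safe
    z[:, ~valid] = 0.0
    return z, valid


def _as_values(x) -> np.ndarray:
    if isinstance(x, VoxelTimeSeriesMatrix):
        return x.values
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2D time-by-node matrix")
    return arr


def _iter_tile_blocks(z: np.ndarray, tile_size: int) -> Iterator[tuple[int, int, np.ndarray]]:
    """Yield (row_offset, col_offset, correlation block) over the upper triangle."""
    n = z.shape[1]
    for a in range(0, n, tile_size):
        za = z[:, a : a + tile_size]
        for b in range(a, n, tile_size):
            block = za.T @ z[:, b : b + tile_size]
            np.clip(block, -1.0, 1.0, out=block)
            yield a, b, block


def _check_pearson_inputs(values: np.ndarray, threshold: float, tile_size: int) -> None:
    if values.shape[0] < 3:
        raise ValueError("need at least 3 time points for correlations")
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")


def pearson_edges(
    x, threshold: float, tile_size: int = DEFAULT_TILE_SIZE
) -> SparseCorrelationGraph:
    """All voxel pairs with |r| >= threshold, computed tile-wise.

    The result is independent of ``tile_size`` (it only bounds working
    memory). Zero-variance columns never form edges but remain as
    isolated nodes.
    """
    values = _as_values(x)
    _check_pearson_inputs(values, threshold, tile_size)
    z, valid = _standardized_columns(values)
    if not valid.any():
        raise ValueError("all columns have zero variance; no correlations defined")
    n = z.shape[1]
    cut = threshold - THRESHOLD_TOL
    ii: list[np.ndarray] = []
    jj: list[np.ndarray] = []
    rr: list[np.ndarray] = []
    for a, b, block in _iter_tile_blocks(z, tile_size):
        hits = np.abs(block) >= cut
        if a == b:  # strict upper triangle of the diagonal block
            hits &= np.triu(np.ones(block.shape, dtype=bool), k=1)
        if not hits.any():
            continue
        loc_i, loc_j = np.nonzero(hits)
        ii.append(loc_i + a)
        jj.append(loc_j + b)
        rr.append(block[loc_i, loc_j])
    if ii:
        edges_i = np.concatenate(ii)
        edges_j = np.concatenate(jj)
        edges_r = np.concatenate(rr)
        order = np.lexsort((edges_j, edges_i))
        edges_i, edges_j, edges_r = edges_i[order], edges_j[order], edges_r[order]
    else:
        edges_i = np.empty(0, dtype=np.intp)
        edges_j = np.empty(0, dtype=np.intp)
        edges_r = np.empty(0, dtype=np.float64)
    index_map = x.index_map if isinstance(x, VoxelTimeSeriesMatrix) else None
    return SparseCorrelationGraph(
        n_nodes=n,
        edges_i=edges_i,
        edges_j=edges_j,
        edges_r=edges_r,
        threshold=float(threshold),
        index_map=index_map,
    )


def build_graph(x, threshold: float, tile_size: int = DEFAULT_TILE_SIZE) -> SparseCorrelationGraph:
    """Graph with all in-mask voxels as nodes and thresholded |r| edges.

    Identical to :func:`pearson_edges`; isolated nodes (including
    zero-variance voxels) are retained, matching a graph whose vertex
    set is the full brain mask.
    """
    return pearson_edges(x, threshold, tile_size=tile_size)


def _abs_correlation_counts(
    z: np.ndarray, thresholds: np.ndarray, tile_size: int
) -> np.ndarray:
    """Number of pairs with |r| >= t (inclusive, with rounding tolerance) per threshold.

    One tiled pass accumulates a histogram of |r| over the quantized
    threshold grid; cumulative sums then give every step of the
    descending scan without storing the dense matrix.
    """
    asc = np.sort(thresholds)
    bin_edges = np.concatenate([asc - THRESHOLD_TOL, [2.0]])
    hist = np.zeros(len(asc), dtype=np.int64)
    for a, b, block in _iter_tile_blocks(z, tile_size):
        if a == b:
            absr = np.abs(block[np.triu_indices(block.shape[0], k=1)])
        else:
            absr = np.abs(block).ravel()
        hist += np.histogram(absr, bins=bin_edges)[0]
    counts_asc = hist[::-1].cumsum()[::-1]  # pairs with |r| >= asc[k]
    # map back to the caller's (descending) threshold order
    pos = np.searchsorted(asc, thresholds)
    return counts_asc[pos]


def select_threshold(
    x,
    s_max: float = 4.0,
    start: float = 1.0,
    step: float = 0.01,
    tile_size: int = DEFAULT_TILE_SIZE,
) -> ThresholdScan:
    """Largest correlation threshold whose graph satisfies S < s_max.

    Scans thresholds ``start, start - step, ...`` downward and returns
    the first (i.e. largest) one whose graph is non-degenerate (E >= 1,
    K > 1) and has S = log(E)/log(K) < s_max. Degenerate graphs do not
    satisfy the criterion: a near-empty graph at high threshold would
    otherwise be selected on pure noise. Raises
    :class:`ThresholdScanError` (carrying the scan table) if no
    threshold >= step qualifies.
    """
    values = _as_values(x)
    if not (0 < step < start <= 1):
        raise ValueError(f"need 0 < step < start <= 1, got step={step}, start={start}")
    _check_pearson_inputs(values, start, tile_size)
    z, valid = _standardized_columns(values)
    if not valid.any():
        raise ValueError("all columns have zero variance; no correlations defined")
    n = z.shape[1]
    n_steps = int(np.floor((start - step) / step + 1e-9)) + 1
    thresholds = np.round(start - step * np.arange(n_steps), 12)
    counts = _abs_correlation_counts(z, thresholds, tile_size)

    rows = []
    selected: tuple[float, SparsitySummary] | None = None
    for t, e in zip(thresholds, counts):
        summ = sparsity_summary(n, int(e))
        s = summ.s_value
        rows.append(
            {
                "threshold": float(t),
                "n_edges": int(e),
                "avg_degree": summ.avg_degree,
                "s": np.nan if s is None else s,
            }
        )
        if summ.s_defined and s < s_max:
            selected = (float(t), summ)
            break
    table = pd.DataFrame(rows, columns=["threshold", "n_edges", "avg_degree", "s"])
    if selected is None:
        raise ThresholdScanError(
            f"no threshold in [{step}, {start}] yields a graph with S < {s_max}",
            scan=table,
        )
    return ThresholdScan(threshold=selected[0], summary=selected[1], table=table)
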