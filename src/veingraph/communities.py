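"""Modularity-based community detection and venous-mask pooling.

Communities are found with the agglomerative fast-greedy scheme
(Clauset–Newman–Moore): start from singleton communities, repeatedly
merge the pair of connected communities with the largest modularity
gain, and cut the merge sequence at the level of maximum modularity

    Q = sum_c ( e_c / m  -  (d_c / 2m)^2 ),

where m is the total edge weight, e_c the weight inside community c and
d_c the community's weighted degree sum. On the sparse graphs this
pipeline produces, whole connected components often end up as single
communities — which is sufficient here, since the goal is groups of
mutually coherent voxels rather than a fine network partition.

Edge weights fed to the optimizer are |r|: thresholding is on the
correlation magnitude, and sign-inverted coherent branches should join
the same community, while modularity with negative weights is
ill-defined for the greedy merge rule. The signed r remains available
on the graph's edges.

Communities of at least ``min_cluster_size`` voxels (default 50) are
pooled into the final venous-voxel mask.

The user-facing entry point is :class:`VeinGraphClustering`, a
scikit-learn style clusterer that chains threshold selection, graph
construction, community detection and pooling; the module functions
expose the individual stages.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .corrgraph import (
    SparseCorrelationGraph,
    SparsitySummary,
    build_graph,
    select_threshold,
)
from .imageio import Mask3D, VoxelIndexMap

__all__ = [
    "Partition",
    "VeinMaskResult",
    "modularity",
    "fast_greedy_partition",
    "pool_large_clusters",
    "VeinGraphClustering",
]


@dataclass
class Partition:
    """A hard node partition with its modularity.

    For partitions produced by :func:`fast_greedy_partition`,
    ``q_trace`` records modularity after each merge and ``cut_step`` the
    merge count at which the dendrogram was cut.
    """

    labels: np.ndarray  # (n_nodes,) community ids 0..C-1
    sizes: np.ndarray  # (C,) community sizes
    modularity: float
    q_trace: np.ndarray | None = None
    cut_step: int | None = None

    @property
    def n_communities(self) -> int:
        return len(self.sizes)


@dataclass
class VeinMaskResult:
    """Pooled mask of all communities at or above the size threshold."""

    mask: Mask3D
    included_clusters: list[tuple[int, int]]  # (community id, size), largest first
    min_size: int

    @property
    def n_voxels(self) -> int:
        return self.mask.n_voxels


def _edge_weights(g: SparseCorrelationGraph, weights=None) -> np.ndarray:
    if weights is None:
        return np.abs(g.edges_r)
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != g.edges_r.shape:
        raise ValueError("need one weight per edge")
    if np.any(w < 0):
        raise ValueError("edge weights must be non-negative")
    return w


def modularity(g: SparseCorrelationGraph, labels, weights=None) -> float:
    """Weighted modularity Q of a labeling; weights default to |r|."""
    labels = np.asarray(labels)
    if labels.shape != (g.n_nodes,):
        raise ValueError("labels must cover every node exactly once")
    w = _edge_weights(g, weights)
    m = w.sum()
    if m <= 0:
        raise ValueError("graph has zero total edge weight; modularity undefined")
    n_comm = int(labels.max()) + 1 if g.n_nodes else 0
    intra = np.bincount(
        labels[g.edges_i], weights=w * (labels[g.edges_i] == labels[g.edges_j]),
        minlength=n_comm,
    )
    node_deg = np.bincount(g.edges_i, weights=w, minlength=g.n_nodes)
    node_deg += np.bincount(g.edges_j, weights=w, minlength=g.n_nodes)
    comm_deg = np.bincount(labels, weights=node_deg, minlength=n_comm)
    return float((intra / m - (comm_deg / (2 * m)) ** 2).sum())


def _canonical_labels(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel community ids to 0..C-1 in order of first appearance."""
    _, labels = np.unique(raw, return_inverse=True)
    # np.unique sorts by representative id == smallest member, which is
    # already the order of first appearance for our representatives
    sizes = np.bincount(labels)
    return labels, sizes


def fast_greedy_partition(g: SparseCorrelationGraph, weights=None) -> Partition:
    """Fast-greedy modularity optimization, cut at the maximum-Q merge level.

    Deterministic: among equal modularity gains the merge with the
    lexicographically smallest pair of community ids is taken
    (communities are identified by their smallest member node), and
    among merge levels of equal Q the one with fewer communities wins.
    Isolated nodes remain singleton communities; an edgeless graph
    yields all singletons with Q defined as 0.
    """
    n = g.n_nodes
    w = _edge_weights(g, weights)
    m = w.sum()
    if g.n_edges == 0 or m <= 0:
        return Partition(
            labels=np.arange(n, dtype=np.intp),
            sizes=np.ones(n, dtype=np.intp),
            modularity=0.0,
            q_trace=np.empty(0),
            cut_step=0,
        )

    # community state, keyed by representative node id
    adj: dict[int, dict[int, float]] = {}
    deg = np.zeros(n, dtype=np.float64)
    for i, j, wij in zip(g.edges_i.tolist(), g.edges_j.tolist(), w.tolist()):
        if i == j:
            continue
        adj.setdefault(i, {})[j] = adj.get(i, {}).get(j, 0.0) + wij
        adj.setdefault(j, {})[i] = adj.get(j, {}).get(i, 0.0) + wij
        deg[i] += wij
        deg[j] += wij

    two_m = 2.0 * m
    q = -float(((deg / two_m) ** 2).sum())  # all-singletons modularity
    version = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)

    def gain(a: int, b: int) -> float:
        return adj[a][b] / m - deg[a] * deg[b] / (two_m * two_m) * 2.0

    heap: list[tuple[float, int, int, int, int]] = []
    for a, nbrs in adj.items():
        for b in nbrs:
            if a < b:
                heap.append((-gain(a, b), a, b, 0, 0))
    heapq.heapify(heap)

    merges: list[tuple[int, int]] = []
    q_trace: list[float] = []
    best_q, best_step = q, 0

    while heap:
        neg_dq, a, b, va, vb = heapq.heappop(heap)
        if not (alive[a] and alive[b]) or version[a] != va or version[b] != vb:
            continue
        # merge b into a (a < b by construction)
        q += -neg_dq
        merges.append((a, b))
        q_trace.append(q)
        deg[a] += deg[b]
        alive[b] = False
        version[a] += 1
        nbrs_a = adj[a]
        for x, wbx in adj.pop(b).items():
            if x == a:
                continue
            adj[x].pop(b, None)
            nbrs_a[x] = nbrs_a.get(x, 0.0) + wbx
            adj[x][a] = nbrs_a[x]
        nbrs_a.pop(b, None)
        for x in nbrs_a:
            lo, hi = (a, x) if a < x else (x, a)
            heapq.heappush(heap, (-gain(lo, hi), lo, hi, version[lo], version[hi]))
        if q >= best_q - 1e-12:  # ties resolved toward fewer communities
            best_q, best_step = q, len(merges)

    # replay the first best_step merges through a union-find
    parent = np.arange(n, dtype=np.intp)

    def find(u: int) -> int:
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for a, b in merges[:best_step]:
        ra, rb = find(a), find(b)
        keep, drop = (ra, rb) if ra < rb else (rb, ra)
        parent[drop] = keep

    raw = np.fromiter((find(u) for u in range(n)), dtype=np.intp, count=n)
    labels, sizes = _canonical_labels(raw)
    return Partition(
        labels=labels,
        sizes=sizes,
        modularity=float(best_q),
        q_trace=np.asarray(q_trace),
        cut_step=best_step,
    )


def pool_large_clusters(
    p: Partition,
    index_map: VoxelIndexMap,
    brain: Mask3D,
    min_size: int = 50,
) -> VeinMaskResult:
    """Union of all communities with >= min_size voxels, rendered as a 3D mask."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if len(p.labels) != index_map.n_nodes:
        raise ValueError("partition labels inconsistent with index map")
    include = p.sizes >= min_size
    node_in = include[p.labels]
    vol = np.zeros(brain.data.shape, dtype=np.uint8)
    coords = index_map.coords[node_in]
    vol[coords[:, 0], coords[:, 1], coords[:, 2]] = 1
    if np.any(vol.astype(bool) & ~brain.data):
        raise ValueError("pooled mask extends outside the brain mask")
    included = [
        (int(cid), int(sz))
        for cid, sz in enumerate(p.sizes.tolist())
        if sz >= min_size
    ]
    included.sort(key=lambda t: (-t[1], t[0]))
    mask = Mask3D(data=vol, affine=brain.affine)
    return VeinMaskResult(mask=mask, included_clusters=included, min_size=int(min_size))


class VeinGraphClustering(ClusterMixin, BaseEstimator):
    """Cluster voxels by thresholded-correlation graph modularity.

    Input samples are voxels, features are time points: ``X`` has shape
    ``(n_voxels, n_timepoints)``. Fitting (1) selects the largest
    correlation threshold whose graph satisfies the sparsity criterion
    S = log(E)/log(K) < ``s_max`` (unless ``threshold`` is fixed),
    (2) builds the sparse |r|-thresholded graph, (3) partitions it by
    fast-greedy modularity optimization, and (4) flags voxels belonging
    to communities of at least ``min_cluster_size`` members — the
    putative venous voxels.

    Parameters
    ----------
    s_max : float, default 4.0
        Sparsity bound for threshold selection.
    threshold : float or None, default None
        Fixed |r| cutoff; ``None`` runs the descending scan.
    scan_start, scan_step : float, default 1.0, 0.01
        Scan grid: thresholds start, start-step, ... are tried in order.
    min_cluster_size : int, default 50
        Minimum community size pooled into the venous mask.
    tile_size : int, default 1024
        Column tile width of the correlation engine (memory bound only;
        results are tile-size invariant).

    Attributes
    ----------
    threshold_ : float
        The |r| cutoff actually used.
    sparsity_ : SparsitySummary
        Edge count / average degree / S of the fitted graph.
    scan_ : pandas.DataFrame or None
        Threshold-scan trajectory (threshold, n_edges, avg_degree, s).
    graph_ : SparseCorrelationGraph
    labels_ : ndarray of shape (n_voxels,)
        Community id per voxel.
    community_sizes_ : ndarray
    modularity_ : float
    is_vein_ : ndarray of bool, shape (n_voxels,)
        True for voxels in communities of >= min_cluster_size members.
    """

    def __init__(
        self,
        s_max: float = 4.0,
        threshold: float | None = None,
        scan_start: float = 1.0,
        scan_step: float = 0.01,
        min_cluster_size: int = 50,
        tile_size: int = 1024,
    ):
        self.s_max = s_max
        self.threshold = threshold
        self.scan_start = scan_start
        self.scan_step = scan_step
        self.min_cluster_size = min_cluster_size
        self.tile_size = tile_size

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_features=3, ensure_min_samples=2)
        values = np.ascontiguousarray(X.T)  # engine wants time x node
        if self.threshold is None:
            scan = select_threshold(
                values,
                s_max=self.s_max,
                start=self.scan_start,
                step=self.scan_step,
                tile_size=self.tile_size,
            )
            self.threshold_ = scan.threshold
            self.scan_ = scan.table
        else:
            self.threshold_ = float(self.threshold)
            self.scan_ = None
        self.graph_ = build_graph(values, self.threshold_, tile_size=self.tile_size)
        self.sparsity_ = self.graph_.summary
        part = fast_greedy_partition(self.graph_)
        self.labels_ = part.labels
        self.community_sizes_ = part.sizes
        self.modularity_ = part.modularity
        self.n_communities_ = part.n_communities
        self.is_vein_ = part.sizes[part.labels] >= self.min_cluster_size
        return self

    @property
    def partition_(self) -> Partition:
        check_is_fitted(self)
        return Partition(
            labels=self.labels_, sizes=self.community_sizes_, modularity=self.modularity_
        )
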