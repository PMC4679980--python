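"""Validation of the pooled venous mask against reference data.

Three comparisons mirror how such a mask is vetted in practice:

* overlap with an externally derived vein mask (e.g. segmented SWI),
  optionally extended by the "brain edge" — the in-brain rim removed by
  eroding the brain mask with a cubic kernel, where superficial veins
  live;
* a Welch two-sample test of temporal SD inside vs. outside the mask
  (venous voxels carry systematically larger BOLD fluctuations);
* seed-based correlation maps, to inspect which voxels a given seed's
  connectivity exceeds the graph-binarization threshold at.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .corrgraph import THRESHOLD_TOL
from .imageio import Mask3D, check_same_grid
from .preprocess import SDMap, VoxelTimeSeriesMatrix

__all__ = [
    "OverlapReport",
    "SDComparison",
    "SeedCorrelationResult",
    "brain_edge",
    "overlap_report",
    "sd_comparison",
    "seed_correlation_map",
]


@dataclass(frozen=True)
class OverlapReport:
    """Fractions of the clustering mask explained by veins and brain edge."""

    n_cluster_voxels: int
    n_brain_voxels: int
    frac_of_brain: float
    frac_in_vein: float
    frac_in_vein_or_edge: float


@dataclass(frozen=True)
class SDComparison:
    """Welch test of temporal SD inside vs. outside the clustering mask."""

    mean_sd_in: float
    mean_sd_out: float
    statistic: float
    p_value: float


@dataclass
class SeedCorrelationResult:
    """Correlation of one seed voxel against every in-mask voxel."""

    rmap: np.ndarray  # 3D, signed r; 0 outside the analysis mask
    display_mask: np.ndarray  # 3D bool, |r| >= display_threshold
    graph_mask: np.ndarray | None  # 3D bool, |r| >= graph threshold (if given)


def brain_edge(brain: Mask3D, kernel_width: int = 5) -> Mask3D:
    """In-brain rim removed by box-kernel erosion of the brain mask.

    The erosion treats out-of-volume neighbours as background, so edges
    at the volume border are conservative. A mask thinner than the
    kernel erodes to nothing, making the whole mask "edge".
    """
    if kernel_width % 2 == 0 or kernel_width < 3:
        raise ValueError(f"kernel width must be odd and >= 3, got {kernel_width}")
    structure = np.ones((kernel_width,) * 3, dtype=bool)
    eroded = ndimage.binary_erosion(brain.data, structure=structure, border_value=0)
    return Mask3D(data=(brain.data & ~eroded).astype(np.uint8), affine=brain.affine)


def overlap_report(
    cluster_mask: Mask3D,
    vein_mask: Mask3D,
    brain: Mask3D,
    kernel_width: int = 5,
) -> OverlapReport:
    """Proportions of clustering-mask voxels inside the vein mask / vein-or-edge."""
    check_same_grid(cluster_mask, vein_mask, "cluster and vein masks")
    check_same_grid(cluster_mask, brain, "cluster and brain masks")
    n_cluster = cluster_mask.n_voxels
    if n_cluster == 0:
        raise ValueError("cluster mask is empty; overlap fractions undefined")
    edge = brain_edge(brain, kernel_width=kernel_width)
    c = cluster_mask.data
    in_vein = int((c & vein_mask.data).sum())
    in_vein_or_edge = int((c & (vein_mask.data | edge.data)).sum())
    return OverlapReport(
        n_cluster_voxels=n_cluster,
        n_brain_voxels=brain.n_voxels,
        frac_of_brain=n_cluster / brain.n_voxels,
        frac_in_vein=in_vein / n_cluster,
        frac_in_vein_or_edge=in_vein_or_edge / n_cluster,
    )


def sd_comparison(sd: SDMap, cluster_mask: Mask3D, brain: Mask3D) -> SDComparison:
    """Welch (unequal-variance) t-test of SD inside vs. outside the cluster mask.

    Both groups are restricted to the brain mask.
    """
    check_same_grid(cluster_mask, brain, "cluster and brain masks")
    inside = sd.values[cluster_mask.data & brain.data]
    outside = sd.values[brain.data & ~cluster_mask.data]
    if len(inside) < 2 or len(outside) < 2:
        raise ValueError("both groups need at least 2 voxels for the SD comparison")
    stat, p = stats.ttest_ind(inside, outside, equal_var=False)
    return SDComparison(
        mean_sd_in=float(inside.mean()),
        mean_sd_out=float(outside.mean()),
        statistic=float(stat),
        p_value=float(p),
    )


def seed_correlation_map(
    x: VoxelTimeSeriesMatrix,
    seed: tuple[int, int, int],
    display_threshold: float = 0.25,
    graph_threshold: float | None = None,
) -> SeedCorrelationResult:
    """Pearson r of the seed voxel's series against every in-mask voxel.

    ``display_threshold`` controls the binary map typically used for
    visualisation; ``graph_threshold`` (e.g. the subject's selected
    binarization threshold) marks the voxels that would be connected to
    the seed in the graph. Both use the same inclusive |r| rule as the
    graph engine.
    """
    coords = x.index_map.coords
    hit = np.nonzero((coords == np.asarray(seed, dtype=coords.dtype)).all(axis=1))[0]
    if len(hit) == 0:
        raise ValueError(f"seed voxel {tuple(seed)} is outside the analysis mask")
    seed_idx = int(hit[0])
    centered = x.values - x.values.mean(axis=0, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=0))
    if norms[seed_idx] == 0:
        raise ValueError("seed voxel has zero variance")
    valid = norms > 0
    r = np.zeros(x.n_nodes)
    r[valid] = centered[:, valid].T @ (centered[:, seed_idx] / norms[seed_idx])
    r[valid] /= norms[valid]
    np.clip(r, -1.0, 1.0, out=r)
    rmap = x.index_map.to_volume(r)
    display = x.index_map.to_volume(np.abs(r) >= display_threshold - THRESHOLD_TOL)
    graph = None
    if graph_threshold is not None:
        graph = x.index_map.to_volume(np.abs(r) >= graph_threshold - THRESHOLD_TOL)
    return SeedCorrelationResult(rmap=rmap, display_mask=display, graph_mask=graph)
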