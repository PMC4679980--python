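"""End-to-end orchestration: filter → matrix → threshold → graph →
communities → venous mask → report.

One invocation processes one subject. The report mirrors the usual
per-subject summary: selected threshold, graph sparsity, included
community sizes, mask size as a fraction of the brain, and — when a
reference vein mask is supplied — the overlap fractions, plus the
in/out SD comparison.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .communities import VeinGraphClustering, VeinMaskResult, pool_large_clusters
from .corrgraph import DEFAULT_TILE_SIZE, SparsitySummary
from .imageio import (
    Mask3D,
    TimeSeriesImage,
    check_same_grid,
    read_mask,
    read_timeseries,
    voxel_index_map,
    write_labels,
    write_mask,
)
from .preprocess import bandpass, extract_matrix, temporal_sd_map
from .validation import OverlapReport, SDComparison, overlap_report, sd_comparison

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "run_pipeline_files",
    "summarize_reports",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables of one pipeline run; defaults are the method's standard values."""

    low_hz: float = 0.01
    high_hz: float = 0.2
    s_max: float = 4.0
    scan_start: float = 1.0
    scan_step: float = 0.01
    tile_size: int = DEFAULT_TILE_SIZE
    min_cluster_size: int = 50
    kernel_width: int = 5
    threshold: float | None = None  # fixed |r| cutoff; None -> scan
    out_dir: str | None = None
    tr: float | None = None  # override for missing header TR


@dataclass
class RunReport:
    """Per-subject summary of one pipeline run."""

    threshold: float
    sparsity: SparsitySummary
    n_communities: int
    included_clusters: list[tuple[int, int]]
    n_mask_voxels: int
    n_brain_voxels: int
    pct_of_brain: float
    modularity: float
    overlap: OverlapReport | None = None
    sd: SDComparison | None = None

    def to_dict(self) -> dict:
        d = {
            "correlation_threshold": self.threshold,
            "n_nodes": self.sparsity.n_nodes,
            "n_edges": self.sparsity.n_edges,
            "avg_degree": self.sparsity.avg_degree,
            "s": self.sparsity.s_value,
            "n_communities": self.n_communities,
            "included_clusters": self.included_clusters,
            "voxels_in_clustering_mask": self.n_mask_voxels,
            "voxels_in_brain_mask": self.n_brain_voxels,
            "pct_of_brain_mask": self.pct_of_brain,
            "modularity": self.modularity,
        }
        if self.overlap is not None:
            d["overlap_with_veins"] = self.overlap.frac_in_vein
            d["overlap_with_veins_or_edge"] = self.overlap.frac_in_vein_or_edge
        if self.sd is not None:
            d.update(
                mean_sd_in_mask=self.sd.mean_sd_in,
                mean_sd_outside_mask=self.sd.mean_sd_out,
                sd_welch_statistic=self.sd.statistic,
                sd_welch_p=self.sd.p_value,
            )
        return d

    def to_text(self) -> str:
        lines = []
        for k, v in self.to_dict().items():
            if isinstance(v, float):
                v = f"{v:.6g}"
            lines.append(f"{k}\t{v}")
        return "\n".join(lines) + "\n"


def run_pipeline(
    bold: TimeSeriesImage,
    brain: Mask3D,
    veins: Mask3D | None = None,
    cfg: RunConfig | None = None,
) -> tuple[RunReport, VeinMaskResult, VeinGraphClustering]:
    """Run the full venous-voxel identification on in-memory images.

    Returns the report, the pooled mask result and the fitted
    :class:`VeinGraphClustering` estimator (whose ``scan_`` attribute
    holds the threshold-scan trajectory). Deterministic for fixed
    inputs and config.
    """
    cfg = cfg or RunConfig()
    check_same_grid(bold, brain, "series and brain mask")
    if veins is not None:
        check_same_grid(brain, veins, "brain and vein masks")

    logger.info("band-pass %.3g-%.3g Hz (tr=%.4g s)", cfg.low_hz, cfg.high_hz, bold.tr)
    filtered = bandpass(bold, cfg.low_hz, cfg.high_hz)
    matrix = extract_matrix(filtered, brain)
    sdmap = temporal_sd_map(filtered, brain)

    model = VeinGraphClustering(
        s_max=cfg.s_max,
        threshold=cfg.threshold,
        scan_start=cfg.scan_start,
        scan_step=cfg.scan_step,
        min_cluster_size=cfg.min_cluster_size,
        tile_size=cfg.tile_size,
    )
    model.fit(matrix.values.T)
    if model.scan_ is not None:
        for row in model.scan_.itertuples(index=False):
            logger.info(
                "scan t=%.2f E=%d K=%.3g S=%s",
                row.threshold, row.n_edges, row.avg_degree,
                "undef" if np.isnan(row.s) else f"{row.s:.3f}",
            )
    logger.info(
        "selected threshold %.2f: E=%d K=%.3g S=%.3f",
        model.threshold_, model.sparsity_.n_edges,
        model.sparsity_.avg_degree, model.sparsity_.s_value,
    )

    result = pool_large_clusters(
        model.partition_, matrix.index_map, brain, min_size=cfg.min_cluster_size
    )
    if result.n_voxels == 0:
        warnings.warn(
            f"no community reached {cfg.min_cluster_size} voxels; "
            "the venous mask is empty",
            stacklevel=2,
        )

    overlap = None
    if veins is not None and result.n_voxels > 0:
        overlap = overlap_report(result.mask, veins, brain, kernel_width=cfg.kernel_width)
    sd = None
    if result.n_voxels >= 2 and brain.n_voxels - result.n_voxels >= 2:
        sd = sd_comparison(sdmap, result.mask, brain)

    report = RunReport(
        threshold=model.threshold_,
        sparsity=model.sparsity_,
        n_communities=model.n_communities_,
        included_clusters=result.included_clusters,
        n_mask_voxels=result.n_voxels,
        n_brain_voxels=brain.n_voxels,
        pct_of_brain=100.0 * result.n_voxels / brain.n_voxels,
        modularity=model.modularity_,
        overlap=overlap,
        sd=sd,
    )

    if cfg.out_dir is not None:
        _persist(Path(cfg.out_dir), report, result, model, matrix.index_map, brain)
    return report, result, model


def _persist(out, report, result, model, index_map, brain) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_mask(result.mask, out / "veinmask.nii.gz")
    labels3d = index_map.to_volume(model.labels_ + 1)  # 0 = background
    write_labels(labels3d, brain.affine, out / "labels.nii.gz")
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    (out / "report.txt").write_text(report.to_text())
    if model.scan_ is not None:
        model.scan_.to_csv(out / "scan_log.tsv", sep="\t", index=False)


def summarize_reports(report_paths) -> pd.DataFrame:
    """Quartile summary of per-subject report.json files.

    Rows follow the usual per-cohort overview (correlation threshold,
    mask size, percentages, overlaps); columns are min / 1st quartile /
    median / mean / 3rd quartile / max across subjects.
    """
    rows = [json.loads(Path(p).read_text()) for p in report_paths]
    if not rows:
        raise ValueError("no reports to summarize")
    keys = [
        "correlation_threshold",
        "voxels_in_brain_mask",
        "voxels_in_clustering_mask",
        "pct_of_brain_mask",
        "overlap_with_veins",
        "overlap_with_veins_or_edge",
    ]
    out = {}
    for k in keys:
        vals = np.array([r[k] for r in rows if k in r], dtype=float)
        if len(vals) == 0:
            continue
        out[k] = {
            "min": vals.min(),
            "q1": np.percentile(vals, 25),
            "median": np.median(vals),
            "mean": vals.mean(),
            "q3": np.percentile(vals, 75),
            "max": vals.max(),
        }
    return pd.DataFrame(out).T


def run_pipeline_files(
    bold_path,
    brain_path,
    veins_path=None,
    cfg: RunConfig | None = None,
) -> tuple[RunReport, VeinMaskResult, VeinGraphClustering]:
    """Path-based wrapper around :func:`run_pipeline`."""
    cfg = cfg or RunConfig()
    bold = read_timeseries(bold_path, tr=cfg.tr)
    brain = read_mask(brain_path)
    veins = read_mask(veins_path) if veins_path is not None else None
    return run_pipeline(bold, brain, veins=veins, cfg=cfg)
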