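"""Volumetric image I/O and the voxel-to-node index mapping.

All volumes are NIfTI-1 (plain or gzip-compressed) read through nibabel.
The pipeline operates on a single voxel grid: 4D BOLD series, brain mask
and (optional) vein mask must share spatial shape and affine. No
resampling or coregistration is performed here — inputs are expected to
be aligned already (EPI space).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "TimeSeriesImage",
    "Mask3D",
    "VoxelIndexMap",
    "read_timeseries",
    "read_mask",
    "write_mask",
    "write_timeseries",
    "write_labels",
    "voxel_index_map",
    "check_same_grid",
]

#: maximum absolute affine difference tolerated between paired volumes
AFFINE_TOL = 1e-4


@dataclass
class TimeSeriesImage:
    """A 4D BOLD series: ``data[x, y, z, t]`` plus grid metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, nt)
        Signal values; arbitrary units, must be finite.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform.
    tr : float
        Repetition time in seconds (> 0). Drives the band-pass design,
        so it is never guessed: missing header TRs must be supplied
        explicitly by the caller.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected a 4D array, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("time series needs at least 2 volumes")
        if not (self.tr > 0):
            raise ValueError(f"repetition time must be positive, got {self.tr}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, derived from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class Mask3D:
    """A binary 3D volume on the same grid as a :class:`TimeSeriesImage`."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D mask, got {arr.ndim}D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("mask values must be binary (0/1)")
        self.data = arr.astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class VoxelIndexMap:
    """Deterministic bijection between in-mask voxels and node indices.

    Nodes are ordered by a row-major (C-order) scan of the mask, so node
    ``j`` lives at voxel ``coords[j]`` and the mapping is stable across
    calls for the same mask.
    """

    coords: np.ndarray  # (n_nodes, 3) int
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.intp)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    def to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter one value per node back into a 3D volume."""
        values = np.asarray(values)
        if values.shape[0] != self.n_nodes:
            raise ValueError("one value per node required")
        vol = np.full(self.shape, fill, dtype=values.dtype)
        vol[self.coords[:, 0], self.coords[:, 1], self.coords[:, 2]] = values
        return vol


def voxel_index_map(mask: Mask3D) -> VoxelIndexMap:
    """Enumerate in-mask voxels in row-major order."""
    if mask.n_voxels == 0:
        raise ValueError("mask is empty: no voxels to index")
    coords = np.argwhere(mask.data)  # C-order scan: deterministic
    return VoxelIndexMap(coords=coords, shape=mask.data.shape)


def check_same_grid(a, b, what: str = "volumes") -> None:
    """Refuse to pair volumes whose grids disagree."""
    shape_a = a.shape3d if isinstance(a, TimeSeriesImage) else a.data.shape
    shape_b = b.shape3d if isinstance(b, TimeSeriesImage) else b.data.shape
    if tuple(shape_a) != tuple(shape_b):
        raise ValueError(f"{what} have different shapes: {shape_a} vs {shape_b}")
    if np.max(np.abs(a.affine - b.affine)) > AFFINE_TOL:
        raise ValueError(f"{what} have different affines (max abs diff > {AFFINE_TOL})")


def _tr_from_header(img: nib.Nifti1Image) -> float:
    zooms = img.header.get_zooms()
    if len(zooms) < 4:
        return 0.0
    tr = float(zooms[3])
    _, t_unit = img.header.get_xyzt_units()
    if t_unit == "msec":
        tr /= 1e3
    elif t_unit == "usec":
        tr /= 1e6
    return tr


def read_timeseries(path, tr: float | None = None) -> TimeSeriesImage:
    """Load a 4D NIfTI series.

    ``tr`` overrides the header value; if the header TR is absent or
    non-positive and no override is given, this raises rather than
    guessing, since TR determines the temporal filter.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: not a time series (expected 4D, got {img.ndim}D)")
    if tr is None:
        tr = _tr_from_header(img)
        if not tr > 0:
            raise ValueError(
                f"{path}: repetition time missing from header; pass tr= explicitly"
            )
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    return TimeSeriesImage(data=data, affine=img.affine, tr=float(tr))


def read_mask(path) -> Mask3D:
    """Load a 3D binary mask; any nonzero voxel counts as inside."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got {data.ndim}D")
    return Mask3D(data=(data != 0).astype(np.uint8), affine=img.affine)


def write_mask(mask: Mask3D, path) -> None:
    """Write a mask as unsigned 8-bit NIfTI-1."""
    _check_writable(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def write_labels(labels3d: np.ndarray, affine: np.ndarray, path) -> None:
    """Write an integer label volume (0 = background)."""
    _check_writable(path)
    img = nib.Nifti1Image(np.asarray(labels3d, dtype=np.int32), affine)
    nib.save(img, str(path))


def write_timeseries(img: TimeSeriesImage, path) -> None:
    _check_writable(path)
    out = nib.Nifti1Image(img.data, img.affine)  # float64: exact round-trips
    out.header.set_zooms((*out.header.get_zooms()[:3], img.tr))
    out.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(out, str(path))


def _check_writable(path) -> None:
    parent = Path(str(path)).parent
    if not parent.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {parent}")
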