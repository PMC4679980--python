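"""Ground-truth resting-state fMRI phantoms.

The phantom emulates exactly the signal structure the graph-clustering
method exploits, with known voxel labels:

* **veins** — a few contiguous, one-voxel-wide branches whose voxels all
  share one band-limited (0.01–0.2 Hz) signal at very high pairwise |r|
  (default target 0.9); some branches carry the signal sign-inverted,
  exercising the absolute-value thresholding. Vein voxels also have
  elevated temporal SD (default 1.8× their local background level).
* **networks** — compact parenchymal blobs sharing a signal at moderate
  pairwise r (default target 0.4), standing in for resting-state
  networks whose correlations must stay below the selected threshold.
* **background** — independent noise everywhere else in the ellipsoidal
  brain mask, with per-voxel SD drawn lognormally so the vein and
  background SD distributions overlap yet differ in mean.

Every temporal component (shared signals and per-voxel noise) is white
noise band-limited to the analysis pass-band and standardized, so the
planted correlation and SD structure survives the pipeline's own
band-pass unchanged. Pairwise correlation targets are met through the
mixing weights: a voxel built as sqrt(rho)·v + sqrt(1-rho)·eps with
unit-variance independent components has correlation rho with any other
voxel built the same way from the same v.

Not modelled: hemodynamics, motion, scanner drift, task structure,
multi-subject variability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .imageio import Mask3D, TimeSeriesImage
from .preprocess import design_bandpass, _filtfilt

__all__ = ["PhantomSpec", "PhantomTruth", "default_spec", "generate_phantom"]

#: isotropic voxel size (mm) of the phantom grid
VOXEL_MM = 3.0

_DIRECTIONS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=np.intp
)


@dataclass
class PhantomSpec:
    """Parameters of the synthetic phantom; defaults define the standard phantom."""

    grid: tuple[int, int, int] = (32, 32, 16)
    t: int = 600
    tr: float = 0.333
    n_vein_branches: int = 3
    vein_voxels_per_branch: int = 100
    flip_fraction: float = 1.0 / 3.0
    vein_r_target: float = 0.9
    n_networks: int = 2
    network_voxels: int = 150
    network_r_target: float = 0.4
    vein_sd_scale: float = 1.8
    noise_sd: float = 1.0
    #: lognormal sigma of the per-voxel background SD heterogeneity
    sd_spread: float = 0.25
    #: pass-band of every temporal component, Hz
    low_hz: float = 0.01
    high_hz: float = 0.2
    baseline: float = 1000.0
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_vein_branches, self.vein_voxels_per_branch, self.n_networks,
               self.network_voxels, self.t) < 1:
            raise ValueError("all counts must be positive")
        if not (0 <= self.flip_fraction <= 1):
            raise ValueError("flip_fraction must be in [0, 1]")
        if not (0 < self.network_r_target < self.vein_r_target <= 1):
            raise ValueError("need 0 < network_r_target < vein_r_target <= 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        if "grid" in d:
            d["grid"] = tuple(d["grid"])
        return cls(**d)


@dataclass
class PhantomTruth:
    """Ground-truth voxel labels emitted alongside the phantom series.

    ``veins`` is the union of ``vein_branches``; ``flipped[b]`` marks
    branches whose shared signal is sign-inverted.
    """

    brain: Mask3D
    veins: Mask3D
    networks: list[Mask3D]
    vein_branches: list[Mask3D] = field(default_factory=list)
    flipped: list[bool] = field(default_factory=list)

    def network_union(self) -> np.ndarray:
        out = np.zeros(self.brain.data.shape, dtype=bool)
        for n in self.networks:
            out |= n.data
        return out


def default_spec() -> PhantomSpec:
    """The standard phantom: 32×32×16 grid, 600 volumes at TR 0.333 s,
    3 vein branches × 100 voxels (one sign-flipped), 2 networks × 150
    voxels, |r| targets 0.9 (vein) / 0.4 (network), vein SD 1.8× background."""
    return PhantomSpec()


def _ellipsoid_mask(grid: tuple[int, int, int]) -> np.ndarray:
    """Brain stand-in: an axis-aligned ellipsoid filling most of the grid.

    Semi-axes are 0.42 of each grid extent — for the default 32×32×16
    grid that is (13.4, 13.4, 6.7), ~4900 voxels.
    """
    nx, ny, nz = grid
    center = (np.array(grid) - 1) / 2.0
    semi = 0.42 * np.array(grid, dtype=float)
    ii, jj, kk = np.ogrid[:nx, :ny, :nz]
    d = (
        ((ii - center[0]) / semi[0]) ** 2
        + ((jj - center[1]) / semi[1]) ** 2
        + ((kk - center[2]) / semi[2]) ** 2
    )
    return d <= 1.0


def _random_walk_branch(
    rng: np.random.Generator, allowed: np.ndarray, length: int, max_restarts: int = 200
) -> np.ndarray:
    """Self-avoiding axis-aligned walk of `length` voxels inside `allowed`.

    Depth-first with backtracking; restarts from a fresh seed voxel if a
    walk dead-ends entirely. Emulates a tubular vein without a vascular
    model.
    """
    free = allowed.copy()
    starts = np.argwhere(free)
    for _ in range(max_restarts):
        start = starts[rng.integers(len(starts))]
        path = [tuple(start)]
        used = {tuple(start)}
        stack = [iter(rng.permutation(6))]
        while path and len(path) < length:
            moved = False
            for d_idx in stack[-1]:
                nxt = tuple(np.asarray(path[-1]) + _DIRECTIONS[d_idx])
                if (
                    all(0 <= c < s for c, s in zip(nxt, free.shape))
                    and free[nxt]
                    and nxt not in used
                ):
                    path.append(nxt)
                    used.add(nxt)
                    stack.append(iter(rng.permutation(6)))
                    moved = True
                    break
            if not moved:
                dropped = path.pop()
                stack.pop()
                # dead branch tip stays in `used` so it is not retried
        if len(path) == length:
            return np.array(path, dtype=np.intp)
    raise RuntimeError("could not place a vein branch; brain too crowded")


def _blob_region(rng: np.random.Generator, allowed: np.ndarray, size: int) -> np.ndarray:
    """Irregular contiguous blob grown voxel-by-voxel from a random seed."""
    starts = np.argwhere(allowed)
    start = tuple(starts[rng.integers(len(starts))])
    region = [start]
    member = {start}
    frontier = [start]
    while len(region) < size:
        if not frontier:
            raise RuntimeError("could not grow a network region; brain too crowded")
        pick = int(rng.integers(len(frontier)))
        base = frontier[pick]
        candidates = []
        for d in _DIRECTIONS:
            nxt = tuple(np.asarray(base) + d)
            if (
                all(0 <= c < s for c, s in zip(nxt, allowed.shape))
                and allowed[nxt]
                and nxt not in member
            ):
                candidates.append(nxt)
        if not candidates:
            frontier.pop(pick)
            continue
        nxt = candidates[int(rng.integers(len(candidates)))]
        region.append(nxt)
        member.add(nxt)
        frontier.append(nxt)
    return np.array(region, dtype=np.intp)


def _band_limited_noise(
    rng: np.random.Generator, shape: tuple[int, ...], sos: np.ndarray
) -> np.ndarray:
    """White noise filtered to the pass-band and standardized to unit sample SD.

    Time runs along axis 0.
    """
    x = rng.standard_normal(shape)
    x = _filtfilt(sos, x, axis=0)
    x = x - x.mean(axis=0, keepdims=True)
    return x / x.std(axis=0, ddof=1, keepdims=True)


def generate_phantom(spec: PhantomSpec) -> tuple[TimeSeriesImage, PhantomTruth]:
    """Build the phantom series and its ground-truth masks.

    Deterministic for a fixed spec (one RNG stream consumed in a fixed
    order: branch geometry, network geometry, shared signals, per-voxel
    noise, per-voxel SD heterogeneity).
    """
    rng = np.random.default_rng(spec.seed)
    brain = _ellipsoid_mask(spec.grid)
    n_brain = int(brain.sum())
    budget = (
        spec.n_vein_branches * spec.vein_voxels_per_branch
        + spec.n_networks * spec.network_voxels
    )
    if budget > n_brain // 2:
        raise ValueError(
            f"vein+network budget ({budget} voxels) exceeds half the brain "
            f"({n_brain} voxels); enlarge the grid"
        )

    free = brain.copy()
    branches: list[np.ndarray] = []
    for _ in range(spec.n_vein_branches):
        path = _random_walk_branch(rng, free, spec.vein_voxels_per_branch)
        free[path[:, 0], path[:, 1], path[:, 2]] = False
        branches.append(path)
    networks: list[np.ndarray] = []
    for _ in range(spec.n_networks):
        region = _blob_region(rng, free, spec.network_voxels)
        free[region[:, 0], region[:, 1], region[:, 2]] = False
        networks.append(region)

    sos = design_bandpass(spec.low_hz, spec.high_hz, spec.tr)
    vein_signal = _band_limited_noise(rng, (spec.t,), sos)
    network_signals = [
        _band_limited_noise(rng, (spec.t,), sos) for _ in range(spec.n_networks)
    ]
    noise = _band_limited_noise(rng, (spec.t, n_brain), sos)
    sigma = spec.noise_sd * np.exp(rng.normal(0.0, spec.sd_spread, size=n_brain))

    # assemble per-voxel series (nodes in row-major brain-mask order)
    coords = np.argwhere(brain)
    flat = {tuple(c): idx for idx, c in enumerate(coords)}
    series = noise.copy()  # background: pure unit-SD noise

    n_flip = int(round(spec.flip_fraction * spec.n_vein_branches))
    a_v = np.sqrt(spec.vein_r_target)
    b_v = np.sqrt(1.0 - spec.vein_r_target)
    for b_idx, path in enumerate(branches):
        sign = -1.0 if b_idx < n_flip else 1.0
        idx = [flat[tuple(c)] for c in path]
        series[:, idx] = (
            sign * a_v * vein_signal[:, None] + b_v * noise[:, idx]
        ) * spec.vein_sd_scale
    a_n = np.sqrt(spec.network_r_target)
    b_n = np.sqrt(1.0 - spec.network_r_target)
    for w, region in zip(network_signals, networks):
        idx = [flat[tuple(c)] for c in region]
        series[:, idx] = a_n * w[:, None] + b_n * noise[:, idx]
    series *= sigma[None, :]
    series += spec.baseline

    data = np.zeros((*spec.grid, spec.t))
    data[brain] = series.T
    affine = np.diag([VOXEL_MM, VOXEL_MM, VOXEL_MM, 1.0])

    vein_vol = np.zeros(spec.grid, dtype=np.uint8)
    branch_masks = []
    for path in branches:
        vein_vol[path[:, 0], path[:, 1], path[:, 2]] = 1
        bv = np.zeros(spec.grid, dtype=np.uint8)
        bv[path[:, 0], path[:, 1], path[:, 2]] = 1
        branch_masks.append(Mask3D(data=bv, affine=affine))
    net_masks = []
    for region in networks:
        v = np.zeros(spec.grid, dtype=np.uint8)
        v[region[:, 0], region[:, 1], region[:, 2]] = 1
        net_masks.append(Mask3D(data=v, affine=affine))

    img = TimeSeriesImage(data=data, affine=affine, tr=spec.tr)
    truth = PhantomTruth(
        brain=Mask3D(data=brain.astype(np.uint8), affine=affine),
        veins=Mask3D(data=vein_vol, affine=affine),
        networks=net_masks,
        vein_branches=branch_masks,
        flipped=[b < n_flip for b in range(spec.n_vein_branches)],
    )
    return img, truth
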