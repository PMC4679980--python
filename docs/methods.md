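# Methods

## Model and rationale

Voxels in and around medium/large veins carry low-frequency BOLD
fluctuations that are far more strongly correlated with each other —
including in anti-phase between branches — than parenchymal voxels of
resting-state networks are in unsmoothed data. The method exploits this
gap: binarize the voxelwise correlation matrix at a very high |r|
threshold, so that essentially only venous coherence survives, then
find the densely intra-connected voxel groups by modularity
optimization and keep the large ones.

The threshold is not fixed a priori but adapted per dataset through the
sparsity criterion S = log E / log K < 4 (E edges, K = 2E/N average
degree): scanning t = 1.00, 0.99, … downward, the first graph
satisfying the criterion is used. Since S = 1 + (log N − log 2)/log K
for fixed N, S falls monotonically as edges accumulate, so the first
hit is the largest satisfying threshold.

## Pipeline stages and defaults

| stage | parameter | default | why |
|---|---|---|---|
| band-pass | pass-band | 0.01–0.2 Hz | isolates low-frequency BOLD; excludes cardiac/respiratory bands |
| band-pass | design | Butterworth order 4, zero-phase (`sosfiltfilt`) | standard resting-state practice; monotone pass-band; no phase distortion |
| graph | scan start / step | 1.0 / 0.01 | threshold grid of the descending scan |
| graph | s_max | 4 | sparsity bound of the selection criterion |
| graph | tile_size | 1024 columns | memory bound of the correlation engine; results are tile-invariant |
| communities | weights | abs(r) | see below |
| pooling | min_cluster_size | 50 voxels | communities this large reflect extended vascular structures |
| validation | erosion kernel | 5×5×5 box | defines the "brain edge" rim where superficial veins sit |

TR is read from the NIfTI header (time units honored) and never
guessed; a missing or zero header TR must be overridden explicitly
because it fixes the filter design.

## Numerical choices

* **Inclusive thresholding.** An edge requires |r| ≥ t − 1e-9. The
  tolerance makes the quantized scan well defined at the boundary —
  e.g. identical series (r = 1 up to float rounding) are connected at
  t = 1.00. Correlations are clamped to [−1, 1] after computation.
* **Degenerate graphs.** At high thresholds the graph may have E = 0 or
  K ≤ 1, where S is undefined (log K ≤ 0). Such graphs are treated as
  *not* satisfying the criterion; otherwise a near-empty noise graph
  would be "selected" at t = 1.0. The scan fails loudly (with the full
  trajectory attached) if no threshold ≥ step qualifies.
* **Scan in one pass.** Instead of re-thresholding per step, one tiled
  sweep histograms |r| over the 0.01 grid; cumulative counts give E(t)
  for every step exactly (same inclusive rule). The dense N×N matrix is
  never stored.
* **Zero-variance voxels** cannot form edges but stay in the graph as
  isolated nodes; the size filter guarantees they never reach the mask.
* **Edge weights for clustering are |r|.** Signed weights are stored on
  the edges, but greedy modularity merging is ill-defined with negative
  weights, and anti-phase venous branches should join one community —
  which |r| achieves. (This is why a sign-flipped phantom branch is
  still recovered.)
* **Fast-greedy determinism.** Among equal modularity gains, the merge
  with the lexicographically smallest pair of community ids wins
  (communities are named by their smallest member). The dendrogram is
  cut at the maximum-modularity level; ties go to the level with fewer
  communities. Node-id permutations therefore change nothing but
  labels.
* **Zero-phase boundary transients.** The 0.01 Hz corner has a filter
  memory of roughly 40 s, so reversal symmetry of the filtered output
  is only exact away from the series boundaries; the symmetry test uses
  a centered pulse on a series long enough for transients to decay.
* **Welch test** (unequal variances) for the in/out SD comparison; the
  two groups have very different sizes and spreads. SD maps are
  computed on the band-passed series, consistent with every other stage
  operating post-filter.

## The synthetic phantom

`generate_phantom` emulates exactly the structure the method assumes,
with ground truth:

* ellipsoidal "brain" (~5000 voxels on the default 32×32×16 grid);
* 3 vein branches of 100 voxels each — axis-aligned self-avoiding
  random walks (tubular, 1 voxel wide) — all sharing one band-limited
  signal, with one branch sign-inverted (flip_fraction 1/3); mixing
  weights √ρ/√(1−ρ) set the pairwise correlation to ρ = 0.9;
* 2 compact 150-voxel "network" blobs, each with its own shared signal
  at pairwise r = 0.4 — high enough to be realistic coherence, low
  enough that the selected threshold must exclude them;
* independent background noise, per-voxel SD drawn lognormal
  (σ = 0.25) so vein SDs (scaled ×1.8) and background SDs overlap yet
  differ in mean;
* every temporal component is white noise band-limited to 0.01–0.2 Hz
  and standardized, so the planted correlation/SD structure passes the
  pipeline's own filter unchanged;
* one RNG stream (default seed 42) consumed in fixed order: vein
  geometry, network geometry, shared signals, voxel noise, SD field —
  bit-identical output per seed.

The default sizes put the scan's stopping point inside the vein-only
regime: 300 mutually coherent voxels offer up to 44 850 edges, while S
crosses 4 near 34 000 edges for ~5000 nodes, so the selected threshold
(≈ 0.88) lands where most vein pairs, and nothing else, are connected.

**What the phantom does not emulate:** hemodynamic response shape,
motion and scanner drift, partial-volume gradations along vessels,
spatial autocorrelation of the noise, susceptibility dropout, or
multi-subject variability. Passing the phantom tests therefore shows
the algorithmic chain is correct under the method's own signal model,
not that real-data overlap figures will reach any particular value;
real acquisitions also run two orders of magnitude more voxels, where
only runtime, not logic, changes (the engine is tiled precisely for
that regime).

## Problem sizes used in tests

The standard phantom (32×32×16 × 600 volumes, ~5000 in-brain voxels)
runs the full pipeline in a few seconds; a 24×24×12 × 400 variant backs
the CLI and determinism tests. Exhaustive modularity oracles enumerate
all partitions up to 10 nodes. These sizes keep the whole suite under a
minute while exercising every code path at realistic sparsity.

## Known limitations

* Fast-greedy merging is O(E·merges) with simple data structures —
  fine up to ~10⁵ edges; whole-brain graphs at very low thresholds
  would warrant a faster heap-sharpened implementation.
* On sparse graphs the algorithm may return entire connected components
  as communities; for vein pooling this is acceptable (the component
  *is* the coherent structure), but the partition should not be
  over-interpreted as fine vascular anatomy.
* Inputs must already share one grid; no registration or resampling is
  provided, and masks/series with mismatched affines are refused.
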