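"""Shared fixtures: phantoms (generated at test time, never stored) and
small graph builders."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import veingraph as vg
from veingraph.corrgraph import SparseCorrelationGraph


def make_graph(n_nodes: int, edges: list[tuple[int, int, float]], threshold: float = 0.0):
    """Build a SparseCorrelationGraph straight from an (i, j, r) edge list."""
    if edges:
        ii, jj, rr = zip(*edges)
    else:
        ii = jj = rr = ()
    return SparseCorrelationGraph(
        n_nodes=n_nodes,
        edges_i=np.array(ii, dtype=np.intp),
        edges_j=np.array(jj, dtype=np.intp),
        edges_r=np.array(rr, dtype=float),
        threshold=threshold,
    )


def clique_edges(nodes: list[int], w: float = 1.0) -> list[tuple[int, int, float]]:
    return [(a, b, w) for k, a in enumerate(nodes) for b in nodes[k + 1 :]]


@pytest.fixture(scope="session")
def default_phantom():
    """The standard phantom (seed 42); shared read-only across the session."""
    return vg.generate_phantom(vg.default_spec())


@pytest.fixture(scope="session")
def phantom_run(default_phantom):
    """Full pipeline run on the standard phantom."""
    img, truth = default_phantom
    report, result, model = vg.run_pipeline(img, truth.brain)
    return report, result, model


@pytest.fixture(scope="session")
def phantom_matrix(default_phantom):
    """Band-passed in-brain voxel-by-time matrix of the standard phantom."""
    img, truth = default_phantom
    filtered = vg.bandpass(img, 0.01, 0.2)
    return vg.extract_matrix(filtered, truth.brain)


@pytest.fixture(scope="session")
def small_spec():
    """A lighter phantom for end-to-end and CLI tests.

    Downscaled while preserving the regime in which the sparsity scan
    terminates among vein edges: 240 vein voxels provide 28k+ potential
    edges against the ~11k at which S crosses 4 for ~2100 brain voxels.
    """
    return replace(
        vg.default_spec(),
        grid=(24, 24, 12),
        t=400,
        n_vein_branches=3,
        vein_voxels_per_branch=80,
        n_networks=2,
        network_voxels=60,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return vg.generate_phantom(small_spec)
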