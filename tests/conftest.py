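"""Shared fixtures: small synthetic geometries and toy meshes."""

import numpy as np
import pytest
from scipy import sparse

from memfuse.geometry import CorticalMesh, HeadModel, build_synthetic_cortex


def mesh_from_edges(n_vertices, edges, vertices=None, normals=None):
    """Build a CorticalMesh from an explicit edge list (graph-only tests)."""
    rows = [a for a, b in edges] + [b for a, b in edges]
    cols = [b for a, b in edges] + [a for a, b in edges]
    adj = sparse.csr_matrix((np.ones(len(rows), dtype=bool), (rows, cols)),
                            shape=(n_vertices, n_vertices))
    if vertices is None:
        vertices = np.column_stack([np.arange(n_vertices, dtype=float),
                                    np.zeros(n_vertices), np.zeros(n_vertices)])
    if normals is None:
        normals = np.tile([0.0, 0.0, 1.0], (n_vertices, 1))
    return CorticalMesh(vertices=np.asarray(vertices, float),
                        faces=np.zeros((0, 3), dtype=int),
                        normals=np.asarray(normals, float), adjacency=adj)


def single_dipole_mesh(position_mm, moment):
    """One-dipole 'mesh' for forward-model point tests."""
    adj = sparse.csr_matrix((1, 1), dtype=bool)
    m = np.asarray(moment, float)
    m = m / np.linalg.norm(m)
    return CorticalMesh(vertices=np.asarray(position_mm, float)[None, :],
                        faces=np.zeros((0, 3), dtype=int),
                        normals=m[None, :], adjacency=adj)


@pytest.fixture(scope="session")
def small_geometry():
    """Folded icosphere cortex (162 vertices) with head model and sensors."""
    return build_synthetic_cortex(n_subdivisions=2, seed=11, n_eeg=24, n_meg=36)


@pytest.fixture(scope="session")
def medium_geometry():
    """642-vertex cortex used by the end-to-end solver tests."""
    return build_synthetic_cortex(n_subdivisions=3, seed=5, n_eeg=32, n_meg=64)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
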