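"""Synthetic cortical geometry, sensor arrays and spherical head models.

The source space is a folded icosphere ("synthetic cortex") placed inside a
three-shell spherical head.  Dipoles sit on the mesh vertices with orientation
fixed along the outward surface normal, mirroring the anatomical constraint
used in cortically-constrained distributed source imaging.  All geometry is
expressed in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class CorticalMesh:
    """Triangulated cortical surface carrying the distributed source model.

    Attributes
    ----------
    vertices : (p, 3) float array, mm
    faces : (f, 3) int array of vertex index triples
    normals : (p, 3) unit outward normals (dipole orientations)
    adjacency : (p, p) sparse boolean vertex graph from shared edges
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray
    adjacency: sparse.csr_matrix

    # flat edge arrays used by the fast neighbourhood kernels
    _indptr: np.ndarray = field(default=None, repr=False)
    _indices: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.normals = np.asarray(self.normals, dtype=float)
        if self._indptr is None:
            csr = self.adjacency.tocsr()
            self._indptr = csr.indptr
            self._indices = csr.indices

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def neighbors(self, v: int) -> np.ndarray:
        return self._indices[self._indptr[v]:self._indptr[v + 1]]

    def vertex_areas(self) -> np.ndarray:
        """Per-vertex area as one third of the adjacent triangle areas (mm^2)."""
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        tri_area = 0.5 * np.linalg.norm(cross, axis=1)
        areas = np.zeros(self.n_vertices)
        for c in range(3):
            np.add.at(areas, self.faces[:, c], tri_area / 3.0)
        return areas


@dataclass
class SensorArray:
    """EEG electrode or MEG magnetometer array.

    positions are in mm; MEG sensors carry unit orientation vectors
    (field projection axes), EEG electrodes do not.
    """

    modality: str
    positions: np.ndarray
    orientations: np.ndarray | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.modality not in ("EEG", "MEG"):
            raise ValueError(f"modality must be EEG or MEG, got {self.modality!r}")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (q, 3)")
        if self.positions.shape[0] < 1:
            raise ValueError("sensor array needs at least one channel")
        if self.orientations is not None:
            self.orientations = np.asarray(self.orientations, dtype=float)
            norms = np.linalg.norm(self.orientations, axis=1, keepdims=True)
            self.orientations = self.orientations / norms
        if self.labels is None:
            pre = "E" if self.modality == "EEG" else "M"
            self.labels = [f"{pre}{i:03d}" for i in range(len(self.positions))]

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    def subset(self, idx: np.ndarray) -> "SensorArray":
        idx = np.asarray(idx, dtype=int)
        return SensorArray(
            modality=self.modality,
            positions=self.positions[idx],
            orientations=None if self.orientations is None else self.orientations[idx],
            labels=[self.labels[i] for i in idx],
        )


@dataclass
class HeadModel:
    """Concentric three-shell spherical head (inner skull, outer skull, scalp)."""

    center: np.ndarray
    radii: np.ndarray          # mm, strictly increasing
    conductivities: np.ndarray  # S/m, brain/skull/scalp

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.conductivities = np.asarray(self.conductivities, dtype=float)
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("head-model radii must be strictly increasing")
        if np.any(self.conductivities <= 0):
            raise ValueError("conductivities must be positive")

    @property
    def rbs(self) -> float:
        """Brain-to-skull conductivity ratio."""
        return self.conductivities[0] / self.conductivities[1]

    def with_rbs(self, rbs: float) -> "HeadModel":
        cond = self.conductivities.copy()
        cond[1] = cond[0] / rbs
        return HeadModel(self.center.copy(), self.radii.copy(), cond)


# ---------------------------------------------------------------------------
# icosphere construction
# ---------------------------------------------------------------------------

def icosphere(n_subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere by repeated edge-midpoint subdivision of an icosahedron.

    Returns (vertices, faces); the vertex count is 10*4**n + 2.
    """
    if n_subdivisions < 0:
        raise ValueError("n_subdivisions must be >= 0")
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=int,
    )
    for _ in range(n_subdivisions):
        verts, faces = _subdivide(verts, faces)
    return verts, faces


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cache: dict[tuple[int, int], int] = {}
    verts_list = list(verts)

    def midpoint(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        if key in cache:
            return cache[key]
        m = verts_list[a] + verts_list[b]
        m = m / np.linalg.norm(m)
        verts_list.append(m)
        cache[key] = len(verts_list) - 1
        return cache[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
    return np.array(verts_list), np.array(new_faces, dtype=int)


def _mesh_from_vertices(vertices: np.ndarray, faces: np.ndarray,
                        center: np.ndarray) -> CorticalMesh:
    """Assemble a CorticalMesh with area-weighted outward vertex normals."""
    tri = vertices[faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # area-weighted
    normals = np.zeros_like(vertices)
    for c in range(3):
        np.add.at(normals, faces[:, c], fn)
    # enforce outward orientation w.r.t. the head centre (star-shaped surface)
    radial = vertices - center
    flip = np.sum(normals * radial, axis=1) < 0
    normals[flip] *= -1.0
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    p = vertices.shape[0]
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = sparse.csr_matrix((np.ones(len(rows), dtype=bool), (rows, cols)),
                            shape=(p, p))
    adj.setdiag(False)
    adj.eliminate_zeros()
    adj.data[:] = True
    return CorticalMesh(vertices=vertices, faces=faces, normals=normals,
                        adjacency=adj)


# ---------------------------------------------------------------------------
# synthetic head + sensors
# ---------------------------------------------------------------------------

DEFAULT_RADII = (71.0, 76.5, 82.0)          # inner skull / outer skull / scalp, mm
DEFAULT_CONDUCTIVITIES = (0.33, 0.0165, 0.33)  # S/m, brain-to-skull ratio 1:20
DEFAULT_CORTEX_RADIUS = 63.0
MEG_HELMET_RADIUS = 102.0


def _fibonacci_cap(n: int, radius: float, z_min_frac: float) -> np.ndarray:
    """n quasi-uniform points on the spherical cap z >= z_min_frac * radius."""
    k = np.arange(n)
    z = z_min_frac + (1.0 - z_min_frac) * (k + 0.5) / n
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * k
    rho = np.sqrt(np.clip(1.0 - z ** 2, 0.0, None))
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return radius * pts


def build_synthetic_cortex(
    n_subdivisions: int = 4,
    folding_amplitude: float = 0.08,
    folding_frequency: float = 6.0,
    seed: int = 0,
    cortex_radius: float = DEFAULT_CORTEX_RADIUS,
    radii: tuple[float, float, float] = DEFAULT_RADII,
    conductivities: tuple[float, float, float] = DEFAULT_CONDUCTIVITIES,
    n_eeg: int = 54,
    n_meg: int = 272,
) -> tuple[CorticalMesh, HeadModel, SensorArray, SensorArray]:
    """Build the full synthetic geometry: folded cortex, head model, sensors.

    The cortex is an icosphere of base radius ``cortex_radius`` whose radius is
    modulated by a smooth pseudo-random ridge pattern (sum of oriented
    sinusoids), emulating sulci/gyri so that dipole orientations and depths
    vary.  ``folding_amplitude`` is the relative radial modulation; the folded
    surface must stay strictly inside the inner-skull sphere.  EEG electrodes
    are laid quasi-uniformly on a scalp cap; MEG sensors are radial
    magnetometers on a helmet sphere above the scalp.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    verts, faces = icosphere(n_subdivisions)

    if folding_amplitude > 0:
        n_waves = 6
        dirs = rng.normal(size=(n_waves, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        phases = rng.uniform(0, 2 * np.pi, size=n_waves)
        mod = np.zeros(len(verts))
        for d, ph in zip(dirs, phases):
            mod += np.sin(folding_frequency * (verts @ d) + ph)
        mod /= n_waves
        radius = cortex_radius * (1.0 + folding_amplitude * mod)
    else:
        radius = np.full(len(verts), float(cortex_radius))

    if np.max(radius) >= radii[0]:
        raise ValueError(
            f"folded cortex reaches {np.max(radius):.1f} mm, outside the "
            f"inner-skull radius {radii[0]:.1f} mm"
        )

    center = np.zeros(3)
    mesh = _mesh_from_vertices(verts * radius[:, None], faces, center)
    head = HeadModel(center=center, radii=np.array(radii),
                     conductivities=np.array(conductivities))

    eeg = SensorArray("EEG", _fibonacci_cap(n_eeg, radii[2], z_min_frac=-0.30))
    meg_pos = _fibonacci_cap(n_meg, MEG_HELMET_RADIUS, z_min_frac=-0.20)
    meg_ori = meg_pos / np.linalg.norm(meg_pos, axis=1, keepdims=True)
    meg = SensorArray("MEG", meg_pos, orientations=meg_ori)
    return mesh, head, eeg, meg


def montage_subset(array: SensorArray, n: int) -> SensorArray:
    """Down-sample a sensor array to n channels by farthest-point sampling.

    Deterministic: starts from the channel closest to the vertex (+z) and
    greedily adds the channel farthest from the selected set, mimicking the
    reduced clinical montages (e.g. 32- or 20-electrode caps).
    """
    if n > array.n_channels:
        raise ValueError("cannot subsample to more channels than available")
    pos = array.positions
    chosen = [int(np.argmax(pos[:, 2]))]
    d = np.linalg.norm(pos - pos[chosen[0]], axis=1)
    while len(chosen) < n:
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(pos - pos[nxt], axis=1))
    return array.subset(np.sort(chosen))


# ---------------------------------------------------------------------------
# graph neighbourhoods and eccentricity
# ---------------------------------------------------------------------------

def kring_neighborhood(mesh: CorticalMesh, seed_vertex: int, order: int) -> np.ndarray:
    """Vertices within graph distance ``order`` of a seed (the seed included).

    This is the mesh "spatial neighbourhood order" used both for growing
    simulated patches and for setting the parcel scale.
    """
    p = mesh.n_vertices
    if not (0 <= seed_vertex < p):
        raise IndexError(f"seed vertex {seed_vertex} out of range [0, {p})")
    if order < 0:
        raise ValueError("order must be >= 0")
    dist = graph_distances(mesh, np.array([seed_vertex]), max_order=order)
    return np.flatnonzero(dist <= order)


def graph_distances(mesh: CorticalMesh, sources: np.ndarray,
                    max_order: int | None = None) -> np.ndarray:
    """Multi-source BFS edge distances from a set of vertices (inf if unreached)."""
    p = mesh.n_vertices
    dist = np.full(p, np.inf)
    dist[np.asarray(sources, dtype=int)] = 0
    frontier = np.asarray(sources, dtype=int)
    d = 0
    while frontier.size and (max_order is None or d < max_order):
        d += 1
        nxt = []
        for v in frontier:
            for u in mesh.neighbors(v):
                if dist[u] == np.inf:
                    dist[u] = d
                    nxt.append(u)
        frontier = np.array(nxt, dtype=int)
    return dist


def eccentricity(patch: np.ndarray, mesh: CorticalMesh, head: HeadModel) -> float:
    """Mean Euclidean distance (mm) of the patch vertices to the head centre.

    A proxy for source depth: the larger the eccentricity the more superficial
    the patch.
    """
    patch = np.asarray(patch, dtype=int)
    if patch.size == 0:
        raise ValueError("patch is empty")
    d = np.linalg.norm(mesh.vertices[patch] - head.center, axis=1)
    return float(np.mean(d))


#: depth-class boundaries (mm): superficial above, deep below, mesial between
ECCENTRICITY_SUPERFICIAL_MM = 80.0
ECCENTRICITY_DEEP_MM = 60.0


def classify_eccentricity(ecc_mm: float) -> str:
    if ecc_mm > ECCENTRICITY_SUPERFICIAL_MM:
        return "superficial"
    if ecc_mm < ECCENTRICITY_DEEP_MM:
        return "deep"
    return "mesial"
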