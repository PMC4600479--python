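"""Validation metrics against simulated ground truth.

AUC measures detection of the true patch from the reconstructed energy map at
the spike peak, with a balanced inactive set drawn half from the patch's
immediate surround (hard negatives) and half from the remaining cortex; SD
(spatial dispersion, mm) is the energy-weighted RMS distance of the estimate
from the patch; SE (shape error) compares normalised patch-mean time courses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .geometry import CorticalMesh, graph_distances


@dataclass
class MetricsRecord:
    """Tidy per-(simulation, arm, source) evaluation row."""

    simulation: int
    method: str
    modality: str
    source: int
    auc: float
    sd_mm: float
    se: float | None
    ic: float | None
    eccentricity_mm: float | None
    snr: float | None
    peak_sample: int


def _mannwhitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Tie-corrected pairwise AUC (equivalent to trapezoidal ROC area)."""
    scores = np.concatenate([pos, neg])
    ranks = rankdata(scores)
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2.0)
                 / (len(pos) * len(neg)))


def roc_auc(
    energy: np.ndarray,
    patch: np.ndarray,
    mesh: CorticalMesh,
    exclude: np.ndarray | None = None,
    n_draws: int = 10,
    seed: int | np.random.Generator = 0,
) -> float:
    """Detection AUC of the true patch from a non-negative energy map.

    For each draw, one negative set of the patch's size is sampled from the
    nearest non-patch vertices (the surround, graph-distance ordered) and one
    from the remaining cortex; the two resulting AUCs are averaged, then
    averaged over draws.  ``exclude`` removes vertices (e.g. the second
    source of a propagation simulation) from the evaluation entirely.
    """
    energy = np.abs(np.asarray(energy, dtype=float))
    patch = np.asarray(patch, dtype=int)
    if patch.size == 0:
        raise ValueError("empty ground-truth patch")
    p = mesh.n_vertices

    banned = np.zeros(p, dtype=bool)
    if exclude is not None:
        banned[np.asarray(exclude, dtype=int)] = True
    is_pos = np.zeros(p, dtype=bool)
    is_pos[patch] = True

    dist = graph_distances(mesh, patch)
    candidates = np.flatnonzero(~is_pos & ~banned)
    if candidates.size == 0:
        raise ValueError("patch covers all evaluable vertices: no negatives")
    order = candidates[np.argsort(dist[candidates], kind="stable")]
    n_pos = patch.size
    n_neg = min(n_pos, candidates.size)
    n_close_pool = min(2 * n_neg, order.size)
    close_pool = order[:n_close_pool]
    far_pool = order[n_close_pool:]
    if far_pool.size == 0:
        far_pool = close_pool

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos_scores = energy[patch]
    aucs = []
    for _ in range(n_draws):
        close = rng.choice(close_pool, size=min(n_neg, close_pool.size),
                           replace=False)
        far = rng.choice(far_pool, size=min(n_neg, far_pool.size),
                         replace=False)
        a_close = _mannwhitney_auc(pos_scores, energy[close])
        a_far = _mannwhitney_auc(pos_scores, energy[far])
        aucs.append(0.5 * (a_close + a_far))
    return float(np.mean(aucs))


def spatial_dispersion(j_peak: np.ndarray, patch: np.ndarray,
                       vertices: np.ndarray) -> float:
    """Spatial dispersion (mm) of an estimate around the true patch.

    SD = sqrt( sum_i min_{j in patch} D(i,j)^2 * J_i^2 / sum_i J_i^2 ), with
    D the Euclidean inter-vertex distance and D = 0 inside the patch.  Zero
    iff all reconstructed energy lies within the patch.
    """
    j_peak = np.asarray(j_peak, dtype=float)
    patch = np.asarray(patch, dtype=int)
    if patch.size == 0:
        raise ValueError("empty patch")
    energy = j_peak ** 2
    total = energy.sum()
    if total == 0:
        raise ValueError("all-zero estimate: SD undefined")
    vertices = np.asarray(vertices, dtype=float)
    # min distance to the patch, computed patch-chunk-wise to bound memory
    d2min = np.full(vertices.shape[0], np.inf)
    for start in range(0, patch.size, 256):
        block = vertices[patch[start:start + 256]]
        diff = vertices[:, None, :] - block[None, :, :]
        d2min = np.minimum(d2min, np.einsum("ipk,ipk->ip", diff, diff).min(axis=1))
    d2min[patch] = 0.0
    return float(np.sqrt(np.sum(d2min * energy) / total))


def shape_error(jth: np.ndarray, j_hat: np.ndarray, patch: np.ndarray,
                window: np.ndarray | slice | None = None) -> float:
    """RMS mismatch of peak-normalised patch-mean time courses.

    Both the ground truth and the estimate are reduced to the mean absolute
    current over the patch (each matrix first normalised by its own maximum
    absolute value), each mean time course is normalised to unit peak over
    the window, and the RMS of the difference is returned.  Invariant to
    positive rescaling of either argument.
    """
    patch = np.asarray(patch, dtype=int)
    if patch.size == 0:
        raise ValueError("empty patch")
    jth = np.atleast_2d(np.asarray(jth, dtype=float))
    j_hat = np.atleast_2d(np.asarray(j_hat, dtype=float))
    if window is not None:
        jth = jth[:, window]
        j_hat = j_hat[:, window]

    def mean_course(J):
        sub = np.abs(J[patch])
        peak = sub.max()
        if peak == 0:
            raise ValueError("all-zero current within the patch over the window")
        m = sub.mean(axis=0) / peak
        return m / np.max(np.abs(m))

    diff = mean_course(jth) - mean_course(j_hat)
    return float(np.sqrt(np.mean(diff ** 2)))
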