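"""Analytic spherical-head forward models (lead fields).

EEG uses the classical multilayer concentric-sphere series solution: the
potential of a current dipole in the innermost shell is expanded in Legendre
harmonics and each radial order is propagated through the shells by solving
the interface continuity conditions (potential and radial current density
continuous, zero radial current at the scalp).  MEG uses the Sarvas
closed-form solution for a dipole in a spherically symmetric conductor,
projected onto the sensor orientations.

These analytic models preserve the physical asymmetry that multimodal fusion
exploits: EEG sees both radial and tangential dipoles through the resistive
skull, MEG is blind to radial dipoles and to the skull.

Geometry enters in millimetres; lead fields are returned in SI units
(volts per A*m for EEG, tesla per A*m for MEG), one column per mesh vertex
with the dipole oriented along the outward surface normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CorticalMesh, HeadModel, SensorArray

MM = 1e-3
MU0_OVER_4PI = 1e-7


@dataclass
class LeadField:
    """Gain matrix linking unit dipoles on the mesh to the sensors."""

    G: np.ndarray           # (q, p), SI per A*m
    modality: str
    provenance: str = "analytic"

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if not np.all(np.isfinite(self.G)):
            raise ValueError("lead field contains non-finite entries")

    @property
    def n_channels(self) -> int:
        return self.G.shape[0]

    @property
    def n_sources(self) -> int:
        return self.G.shape[1]

    def subset(self, idx: np.ndarray, rereference: bool = True) -> "LeadField":
        """Row-subset the gain (EEG is re-referenced to the new average)."""
        G = self.G[np.asarray(idx, dtype=int)]
        if self.modality == "EEG" and rereference:
            G = G - G.mean(axis=0, keepdims=True)
        return LeadField(G=G, modality=self.modality, provenance=self.provenance)


def _shell_coefficients(n: int, rho_ifaces: np.ndarray,
                        sigma: np.ndarray) -> tuple[float, float]:
    """Outer-shell potential coefficients (A_N, B_N) for harmonic order n.

    Radii are scaled by the scalp radius so the outer boundary sits at rho=1.
    The source term is a unit ``rho**-(n+1)`` harmonic in the innermost shell.
    """
    n_shell = len(sigma)
    n_unknown = 2 * n_shell - 1
    A = np.zeros((n_unknown, n_unknown))
    b = np.zeros(n_unknown)
    # unknown layout: [A_1, A_2, B_2, ..., A_N, B_N]
    def col_A(j):  # shell index j (0-based)
        return 0 if j == 0 else 2 * j - 1

    def col_B(j):
        return 2 * j

    row = 0
    for j in range(n_shell - 1):
        rho = rho_ifaces[j]
        pw_n = rho ** n
        pw_m = rho ** (-(n + 1))
        dn = n * rho ** (n - 1)
        dm = -(n + 1) * rho ** (-(n + 2))
        # potential continuity
        A[row, col_A(j)] += pw_n
        if j > 0:
            A[row, col_B(j)] += pw_m
        A[row, col_A(j + 1)] -= pw_n
        A[row, col_B(j + 1)] -= pw_m
        b[row] = -pw_m if j == 0 else 0.0
        row += 1
        # radial current continuity
        A[row, col_A(j)] += sigma[j] * dn
        if j > 0:
            A[row, col_B(j)] += sigma[j] * dm
        A[row, col_A(j + 1)] -= sigma[j + 1] * dn
        A[row, col_B(j + 1)] -= sigma[j + 1] * dm
        b[row] = -sigma[j] * dm if j == 0 else 0.0
        row += 1
    # insulating outer boundary at rho = 1
    A[row, col_A(n_shell - 1)] = n
    A[row, col_B(n_shell - 1)] = -(n + 1)
    x = np.linalg.solve(A, b)
    return x[col_A(n_shell - 1)], x[col_B(n_shell - 1)]


def eeg_leadfield_sphere(
    mesh: CorticalMesh,
    head: HeadModel,
    eeg: SensorArray,
    n_terms: int = 60,
    average_reference: bool = True,
) -> LeadField:
    """EEG lead field from the multilayer-sphere Legendre series.

    The series is truncated at ``n_terms`` harmonics (default 60, adequate for
    dipole eccentricities up to ~0.85 of the scalp radius).  With
    ``average_reference`` every column sums to zero over electrodes; the same
    reference must be applied to the measured data.
    """
    if eeg.modality != "EEG":
        raise ValueError("sensor array is not EEG")
    r0 = (mesh.vertices - head.center) * MM       # (p, 3) m
    re = (eeg.positions - head.center) * MM       # (q, 3) m
    radii = head.radii * MM
    sigma = head.conductivities
    L = radii[-1]

    b = np.linalg.norm(r0, axis=1)
    if np.any(b >= radii[0]):
        raise ValueError("all dipoles must lie strictly inside the inner skull")
    if np.any(b <= 0):
        raise ValueError("dipole at the head centre is not supported")
    rho_e = np.linalg.norm(re, axis=1) / L
    if np.any(rho_e < radii[-2] / L - 1e-9):
        raise ValueError("EEG electrodes must lie on/in the scalp shell")
    rho_e = np.clip(rho_e, radii[-2] / L, 1.0)

    r0_hat = r0 / b[:, None]
    re_hat = re / (rho_e[:, None] * L)
    m = mesh.normals                               # unit dipole moments, A*m

    x = re_hat @ r0_hat.T                          # (q, p) cos(gamma)
    q_r = np.einsum("pi,pi->p", m, r0_hat)         # radial moment component
    a_em = re_hat @ m.T                            # (q, p) m . r_hat_e
    T = a_em - x * q_r[None, :]                    # tangential angular factor

    rho_ifaces = radii / L
    t = b / L                                       # scaled dipole radius

    V = np.zeros_like(x)
    P_nm2 = np.ones_like(x)        # P_0
    P_nm1 = x.copy()               # P_1
    dP_nm2 = np.zeros_like(x)      # P_0'
    dP_nm1 = np.ones_like(x)       # P_1'
    # dipole-radius powers b^(n-1), updated multiplicatively
    t_pow = np.ones_like(t)        # t^(n-1) for n = 1
    for n in range(1, n_terms + 1):
        if n == 1:
            P_n, dP_n = P_nm1, dP_nm1
        else:
            P_n = ((2 * n - 1) * x * P_nm1 - (n - 1) * P_nm2) / n
            dP_n = dP_nm2 + (2 * n - 1) * P_nm1
            P_nm2, P_nm1 = P_nm1, P_n
            dP_nm2, dP_nm1 = dP_nm1, dP_n
        A_N, B_N = _shell_coefficients(n, rho_ifaces, sigma)
        phi = A_N * rho_e ** n + B_N * rho_e ** (-(n + 1))     # (q,)
        coef = t_pow / (4.0 * np.pi * sigma[0] * L ** 2)        # (p,)
        V += (phi[:, None] * coef[None, :]) * (n * q_r[None, :] * P_n + T * dP_n)
        t_pow = t_pow * t

    if average_reference:
        V = V - V.mean(axis=0, keepdims=True)
    return LeadField(G=V, modality="EEG")


def meg_leadfield_sphere(
    mesh: CorticalMesh,
    head: HeadModel,
    meg: SensorArray,
) -> LeadField:
    """MEG lead field from the Sarvas spherical-conductor formula.

    The field of a current dipole inside a spherically symmetric conductor is
    closed-form and independent of the conductivity profile; radial dipoles
    and dipoles at the centre are magnetically silent.  The field is projected
    onto each sensor's orientation axis (point magnetometers).
    """
    if meg.modality != "MEG":
        raise ValueError("sensor array is not MEG")
    if meg.orientations is None:
        raise ValueError("MEG sensors need orientation vectors")
    r0 = (mesh.vertices - head.center) * MM      # (p, 3)
    r = (meg.positions - head.center) * MM       # (q, 3)
    if np.any(np.linalg.norm(r0, axis=1) >= head.radii[0] * MM):
        raise ValueError("dipoles must be inside the inner-skull sphere")
    if np.any(np.linalg.norm(r, axis=1) <= head.radii[0] * MM):
        raise ValueError("MEG sensors must be outside the conductor sphere")
    Q = mesh.normals                              # unit moments, A*m

    B = sarvas_field(r, r0, Q)                    # (q, p, 3)
    G = np.einsum("qpi,qi->qp", B, meg.orientations)
    return LeadField(G=G, modality="MEG")


def sarvas_field(sensors: np.ndarray, dipole_pos: np.ndarray,
                 dipole_moment: np.ndarray) -> np.ndarray:
    """Magnetic field (T) of dipoles in a spherical conductor centred at 0.

    Parameters are in SI (m, A*m).  Returns a (q, p, 3) array for q sensor
    positions and p dipoles.
    """
    r = np.asarray(sensors, dtype=float)[:, None, :]        # (q, 1, 3)
    r0 = np.asarray(dipole_pos, dtype=float)[None, :, :]    # (1, p, 3)
    Q = np.asarray(dipole_moment, dtype=float)

    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=-1)
    rn = np.linalg.norm(r, axis=-1)
    adotr = np.einsum("qpi,qpi->qp", a_vec, np.broadcast_to(r, a_vec.shape))
    r0dotr = np.einsum("qpi,qpi->qp", np.broadcast_to(r0, a_vec.shape),
                       np.broadcast_to(r, a_vec.shape))
    F = a * (rn * a + rn ** 2 - r0dotr)
    gradF = ((a ** 2 / rn + adotr / a + 2.0 * a + 2.0 * rn)[..., None] * r
             - (a + 2.0 * rn + adotr / a)[..., None] * r0)
    Qxr0 = np.cross(np.broadcast_to(Q[None, :, :], a_vec.shape),
                    np.broadcast_to(r0, a_vec.shape))
    Qxr0_dot_r = np.einsum("qpi,qpi->qp", Qxr0, np.broadcast_to(r, a_vec.shape))
    B = MU0_OVER_4PI / (F ** 2)[..., None] * (
        F[..., None] * Qxr0 - Qxr0_dot_r[..., None] * gradF
    )
    return B
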