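"""Internal-coordinate backbone construction.

Polypeptide backbones are built atom-by-atom with the natural extension
reference frame (NeRF) construction: each atom is placed from the three
previously placed atoms given a bond length, a bond angle and a dihedral.
Bond lengths and angles are fixed at canonical values (Engh-Huber-class
geometry); conformation is controlled entirely through (phi, psi) with a
trans peptide bond (omega = 180 deg).
"""

from __future__ import annotations

import numpy as np

# canonical backbone geometry, angstroms / degrees
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010

ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

OMEGA_TRANS = 180.0

# ideal conformations used by the trajectory generator
PHI_PSI_HELIX = (-57.0, -47.0)
PHI_PSI_STRAND = (-139.0, 135.0)
PHI_PSI_COIL = (-75.0, 160.0)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given chain A-B-C, |CD| = bond, angle(BCD) and dihedral(ABCD)."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array([
        -np.cos(angle),
        np.sin(angle) * np.cos(dihedral),
        np.sin(angle) * np.sin(dihedral),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_backbone(phi: np.ndarray, psi: np.ndarray) -> dict[str, np.ndarray]:
    """Build an n-residue backbone from per-residue (phi, psi).

    phi[0] is ignored (no preceding carbonyl); returns arrays of shape
    (n, 3) for N, H, CA, C, O.  The amide H is placed in the peptide
    plane opposite the bisector of its two bonded neighbours.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n_res = phi.shape[0]
    if psi.shape[0] != n_res:
        raise ValueError("phi and psi must have equal length")
    if n_res < 1:
        raise ValueError("need at least one residue")

    N = np.empty((n_res, 3))
    CA = np.empty((n_res, 3))
    C = np.empty((n_res, 3))

    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.deg2rad(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, n_res):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                          BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                           BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        C[i] = place_atom(C[i - 1], N[i], CA[i],
                          BOND_CA_C, ANGLE_N_CA_C, phi[i])

    O = np.empty((n_res, 3))
    for i in range(n_res):
        # carbonyl O anti to the next amide N across the C(i) plane
        O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O,
                          psi[i] + 180.0)

    H = np.empty((n_res, 3))
    for i in range(n_res):
        if i == 0:
            u = _unit(N[0] - CA[0])
            v = _unit(N[0] - C[0])
        else:
            u = _unit(N[i] - C[i - 1])
            v = _unit(N[i] - CA[i])
        H[i] = N[i] + BOND_N_H * _unit(u + v)
    return {"N": N, "H": H, "CA": CA, "C": C, "O": O}


def sidechain_anchor(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                     length: float) -> np.ndarray:
    """A single pseudo side-chain atom at `length` angstroms from CA,
    pointing away from the backbone (roughly along an idealised CB)."""
    u1 = _unit(n - ca)
    u2 = _unit(c - ca)
    out = _unit(np.cross(u2, u1))
    direction = _unit(-(u1 + u2) + 1.2 * out)
    return ca + length * direction


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle in degrees (IUPAC convention)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)
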