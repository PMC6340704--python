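"""Low-level backbone geometry: torsion measurement and internal-coordinate building.

Conventions: coordinates are numpy float arrays in Angstrom; angles in degrees.
Dihedrals follow the IUPAC sign convention (right-handed, trans = 180).
"""
from __future__ import annotations

import numpy as np

# Ideal peptide internal coordinates (Engh & Huber-style constants).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANG_C_N_CA = 121.7
ANG_N_CA_C = 111.0
ANG_CA_C_N = 116.2
ANG_CA_C_O = 120.8

_COLLINEAR_EPS = 1e-8


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, NaN for a degenerate quadruple."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < _COLLINEAR_EPS or np.linalg.norm(n2) < _COLLINEAR_EPS:
        return float("nan")
    b1n = b1 / np.linalg.norm(b1)
    m1 = np.cross(n1, b1n)
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF atom placement: returns d with |c-d| = bond, angle(b,c,d) = angle
    and dihedral(a,b,c,d) = torsion."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(ang),
                   bond * np.sin(ang) * np.cos(tor),
                   -bond * np.sin(ang) * np.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_chain(phis, psis, omega: float = 180.0):
    """Build an ideal-geometry backbone from per-residue (phi, psi).

    phis[0] and psis[-1] are ignored (undefined at termini). Returns a dict of
    (nres, 3) arrays for N, CA, C, O.
    """
    nres = len(phis)
    if nres != len(psis):
        raise ValueError("phi and psi lists must have equal length")
    if nres < 2:
        raise ValueError("need at least 2 residues")
    N = [np.zeros(3)]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = np.deg2rad(ANG_N_CA_C)
    C = [CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    O = []
    for i in range(nres - 1):
        psi = psis[i]
        n_next = place_atom(N[i], CA[i], C[i], BOND_C_N, ANG_CA_C_N, psi)
        ca_next = place_atom(CA[i], C[i], n_next, BOND_N_CA, ANG_C_N_CA, omega)
        c_next = place_atom(C[i], n_next, ca_next, BOND_CA_C, ANG_N_CA_C, phis[i + 1])
        O.append(place_atom(N[i], CA[i], C[i], BOND_C_O, ANG_CA_C_O, psi - 180.0))
        N.append(n_next)
        CA.append(ca_next)
        C.append(c_next)
    # last carbonyl: torsion relative to a nominal psi of 180
    O.append(place_atom(N[-1], CA[-1], C[-1], BOND_C_O, ANG_CA_C_O, 0.0))
    return {k: np.asarray(v) for k, v in {"N": N, "CA": CA, "C": C, "O": O}.items()}


def strand_template(phi: float = -120.0, psi: float = 130.0):
    """Per-parity backbone atom offsets of an ideal beta strand.

    Builds a 12-residue ideal strand, fits its axis, and averages the
    perpendicular offsets of N/CA/C/O for even and odd residues in a frame
    (u = carbonyl/H-bond direction of even residues, v = strand axis,
    w = u x v, the pleat normal).

    Returns (offsets, rise) where offsets[parity][atom] is a length-3 vector
    of (u, v, w) components and rise is the axial translation per residue.
    """
    chain = build_chain([phi] * 12, [psi] * 12)
    ca = chain["CA"]
    center = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - center)
    axis = vt[0]
    proj = (ca - center) @ axis
    if proj[-1] < proj[0]:
        axis = -axis
        proj = -proj
    rise = float(np.diff(proj).mean())
    co = chain["O"] - chain["C"]
    co_perp = co - np.outer(co @ axis, axis)
    u_dir = co_perp[2:10:2].mean(axis=0)
    u_dir = u_dir / np.linalg.norm(u_dir)
    w_dir = np.cross(u_dir, axis)
    offsets = {0: {}, 1: {}}
    for atom in ("N", "CA", "C", "O"):
        for parity in (0, 1):
            vals = []
            for i in range(3, 9):
                if i % 2 != parity:
                    continue
                site = center + proj[i] * axis
                d = chain[atom][i] - site
                vals.append((float(d @ u_dir), float(d @ axis), float(d @ w_dir)))
            offsets[parity][atom] = np.mean(vals, axis=0)
    return offsets, rise
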