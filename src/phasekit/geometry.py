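"""Internal-coordinate geometry: NeRF atom placement, CB construction,
ideal backbone generation and side-chain growth."""

from __future__ import annotations

import numpy as np

__all__ = [
    "place_atom",
    "place_cb",
    "dihedral",
    "build_backbone",
    "grow_sidechain",
    "CB_BOND_LENGTH",
]

CB_BOND_LENGTH = 1.53  # CA-CB, Angstrom

# ideal backbone internal coordinates (Engh-Huber-style averages)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0


def place_atom(r1, r2, r3, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement.

    Returns X bonded to r3 with |X - r3| = bond, angle X-r3-r2 and dihedral
    X-r3-r2-r1 as given (degrees).
    """
    r1, r2, r3 = (np.asarray(r, dtype=float) for r in (r1, r2, r3))
    bc = r3 - r2
    bc /= np.linalg.norm(bc)
    ab = r2 - r1
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise ValueError("collinear reference atoms in NeRF placement")
    n /= nn
    m = np.cross(n, bc)
    ang = np.radians(180.0 - angle_deg)
    tor = np.radians(dihedral_deg)
    d = bond * np.array(
        [np.cos(ang), np.sin(ang) * np.cos(tor), -np.sin(ang) * np.sin(tor)]
    )
    return r3 + d[0] * bc + d[1] * m + d[2] * n


def grow_sidechain(res, chis: tuple[float, ...]) -> None:
    """Attach ideal side-chain atoms for ``res.name`` at the given chi angles.

    ``res`` is a Trace residue (atom-name -> position dict); CB is created
    if absent.  Atoms are placed in topology order so parents always exist.
    """
    from .resdata import SIDECHAIN_TOPOLOGY

    topo = SIDECHAIN_TOPOLOGY[res.name]
    if not topo:
        return
    res.ensure_cb()
    for name, _el, parents, bond, angle, dspec in topo:
        if isinstance(dspec, tuple):
            _, k, off = dspec
            tor = chis[k - 1] + off if k - 1 < len(chis) else off
        else:
            tor = dspec
        res.atoms[name] = place_atom(
            res.atoms[parents[0]], res.atoms[parents[1]], res.atoms[parents[2]],
            bond, angle, tor,
        )


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees."""
    p1, p2, p3, p4 = (np.asarray(p) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(m @ n2, n1 @ n2)))


def place_cb(n_pos, ca_pos, c_pos, bond: float = CB_BOND_LENGTH) -> np.ndarray:
    """Ideal tetrahedral CB from the backbone N, CA, C of one residue.

    The two mirror solutions are disambiguated by L-amino-acid chirality
    (positive improper dihedral N-CA-C-CB... i.e. CB on the standard side).
    """
    n_pos, ca_pos, c_pos = (np.asarray(p, dtype=float) for p in (n_pos, ca_pos, c_pos))
    u1 = n_pos - ca_pos
    u1 /= np.linalg.norm(u1)
    u2 = c_pos - ca_pos
    u2 /= np.linalg.norm(u2)
    w = np.cross(u1, u2)
    nw = np.linalg.norm(w)
    if nw < 1e-6:
        raise ValueError("collinear backbone: cannot place CB")
    w /= nw
    # solve v.u1 = cos(110.5 deg), v.u2 = cos(110.1 deg) in the (u1,u2,w) basis
    c1, c2 = np.cos(np.radians(110.5)), np.cos(np.radians(110.1))
    dot = float(u1 @ u2)
    mat = np.array([[1.0, dot], [dot, 1.0]])
    alpha, beta = np.linalg.solve(mat, [c1, c2])
    planar = alpha * u1 + beta * u2
    g2 = 1.0 - float(planar @ planar)
    gamma = np.sqrt(max(g2, 0.0))
    v = planar + gamma * w  # plus sign: positive improper N-CA-C-CB (L side)
    v /= np.linalg.norm(v)
    return ca_pos + bond * v


def build_backbone(n_res: int, phi: float, psi: float, omega: float = OMEGA):
    """Ideal-geometry backbone with constant (phi, psi).

    Returns a list of dicts with keys N, CA, C, O (orthogonal Angstrom).
    The chain starts near the origin and extends along its own axis.
    """
    if n_res < 1:
        raise ValueError("need at least one residue")
    # seed triad
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([BOND_N_CA, 0.0, 0.0])
    c0 = place_atom(
        n0 + np.array([0.0, 1.0, 0.0]), n0, ca0, BOND_CA_C, ANGLE_N_CA_C, 120.0
    )
    residues = [{"N": n0, "CA": ca0, "C": c0}]
    for i in range(1, n_res):
        prev = residues[-1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, omega)
        c_i = place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl O: trans to the next N (or to psi continuation at the C terminus)
    for i, res in enumerate(residues):
        if i + 1 < len(residues):
            ref = residues[i + 1]["N"]
            res["O"] = place_atom(ref, res["CA"], res["C"], BOND_C_O, ANGLE_CA_C_O, 180.0)
        else:
            nxt = place_atom(res["N"], res["CA"], res["C"], BOND_C_N, ANGLE_CA_C_N, psi)
            res["O"] = place_atom(nxt, res["CA"], res["C"], BOND_C_O, ANGLE_CA_C_O, 180.0)
    return residues
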