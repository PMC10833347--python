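"""Bundled residue data: side-chain topologies, rotamers, secondary-structure
propensities and the gamma-class/residue-type compatibility table.

Side-chain atoms are defined in internal coordinates relative to three
parent atoms (NeRF), with dihedrals either fixed or expressed as a chi
angle plus an offset.  Geometry values are ideal-bond averages; ring
closures are approximate, which is adequate for density probing and
scoring (tenth-of-an-Angstrom fidelity, not refinement targets).
"""

from __future__ import annotations

import numpy as np

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AMINO_ACIDS = sorted(AA1_TO_3)  # one-letter, alphabetical

# ---------------------------------------------------------------------------
# Side-chain topology: residue -> list of
# (atom_name, element, (p1, p2, p3), bond, angle, dihedral_spec)
# dihedral_spec: float (fixed degrees) or ("chi", k, offset_degrees)
# Atoms are placed in order; parents may be backbone or earlier side-chain
# atoms.  CB itself comes from the tetrahedral construction, not this table.
# ---------------------------------------------------------------------------
CHI = lambda k, off=0.0: ("chi", k, off)

SIDECHAIN_TOPOLOGY: dict[str, list] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, CHI(1))],
    "CYS": [("SG", "S", ("N", "CA", "CB"), 1.808, 113.8, CHI(1))],
    "THR": [("OG1", "O", ("N", "CA", "CB"), 1.433, 110.5, CHI(1)),
            ("CG2", "C", ("N", "CA", "CB"), 1.521, 111.5, CHI(1, -120.0))],
    "VAL": [("CG1", "C", ("N", "CA", "CB"), 1.527, 110.5, CHI(1)),
            ("CG2", "C", ("N", "CA", "CB"), 1.527, 110.5, CHI(1, 122.0))],
    "ILE": [("CG1", "C", ("N", "CA", "CB"), 1.530, 110.4, CHI(1)),
            ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, CHI(1, -122.0)),
            ("CD1", "C", ("CA", "CB", "CG1"), 1.513, 113.8, CHI(2))],
    "LEU": [("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, CHI(1)),
            ("CD1", "C", ("CA", "CB", "CG"), 1.521, 110.7, CHI(2)),
            ("CD2", "C", ("CA", "CB", "CG"), 1.521, 110.7, CHI(2, 122.0))],
    "PRO": [("CG", "C", ("N", "CA", "CB"), 1.495, 104.5, CHI(1)),
            ("CD", "C", ("CA", "CB", "CG"), 1.507, 105.5, CHI(2))],
    "MET": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, CHI(1)),
            ("SD", "S", ("CA", "CB", "CG"), 1.803, 112.7, CHI(2)),
            ("CE", "C", ("CB", "CG", "SD"), 1.791, 100.9, CHI(3))],
    "PHE": [("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, CHI(1)),
            ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, CHI(2)),
            ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, CHI(2, 180.0)),
            ("CE1", "C", ("CB", "CG", "CD1"), 1.384, 120.8, 180.0),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.384, 120.8, 180.0),
            ("CZ", "C", ("CG", "CD1", "CE1"), 1.384, 120.0, 0.0)],
    "TYR": [("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, CHI(1)),
            ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, CHI(2)),
            ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, CHI(2, 180.0)),
            ("CE1", "C", ("CB", "CG", "CD1"), 1.384, 120.8, 180.0),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.384, 120.8, 180.0),
            ("CZ", "C", ("CG", "CD1", "CE1"), 1.384, 120.0, 0.0),
            ("OH", "O", ("CD1", "CE1", "CZ"), 1.376, 120.0, 180.0)],
    "TRP": [("CG", "C", ("N", "CA", "CB"), 1.498, 113.6, CHI(1)),
            ("CD1", "C", ("CA", "CB", "CG"), 1.365, 126.9, CHI(2)),
            ("CD2", "C", ("CA", "CB", "CG"), 1.433, 126.7, CHI(2, 180.0)),
            ("NE1", "N", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
            ("CE3", "C", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
            ("CZ2", "C", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
            ("CZ3", "C", ("CG", "CD2", "CE3"), 1.382, 118.6, 180.0),
            ("CH2", "C", ("CD2", "CE2", "CZ2"), 1.368, 117.5, 0.0)],
    "ASP": [("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, CHI(1)),
            ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.4, CHI(2)),
            ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.4, CHI(2, 180.0))],
    "ASN": [("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, CHI(1)),
            ("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, CHI(2)),
            ("ND2", "N", ("CA", "CB", "CG"), 1.328, 116.4, CHI(2, 180.0))],
    "GLU": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, CHI(1)),
            ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, CHI(2)),
            ("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.4, CHI(3)),
            ("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.4, CHI(3, 180.0))],
    "GLN": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, CHI(1)),
            ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, CHI(2)),
            ("OE1", "O", ("CB", "CG", "CD"), 1.231, 120.8, CHI(3)),
            ("NE2", "N", ("CB", "CG", "CD"), 1.328, 116.4, CHI(3, 180.0))],
    "LYS": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, CHI(1)),
            ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, CHI(2)),
            ("CE", "C", ("CB", "CG", "CD"), 1.520, 111.3, CHI(3)),
            ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.9, CHI(4))],
    "ARG": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, CHI(1)),
            ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, CHI(2)),
            ("NE", "N", ("CB", "CG", "CD"), 1.461, 112.0, CHI(3)),
            ("CZ", "C", ("CG", "CD", "NE"), 1.329, 124.2, CHI(4)),
            ("NH1", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
            ("NH2", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0)],
    "HIS": [("CG", "C", ("N", "CA", "CB"), 1.497, 113.8, CHI(1)),
            ("ND1", "N", ("CA", "CB", "CG"), 1.371, 122.7, CHI(2)),
            ("CD2", "C", ("CA", "CB", "CG"), 1.356, 131.0, CHI(2, 180.0)),
            ("CE1", "C", ("CB", "CG", "ND1"), 1.319, 109.0, 180.0),
            ("NE2", "N", ("CB", "CG", "CD2"), 1.374, 107.0, 180.0)],
}

# rotamer candidates per residue: list of chi tuples (degrees), most-common
# rotamer per chi1 bucket first
ROTAMERS: dict[str, list[tuple[float, ...]]] = {
    "SER": [(-60.0,), (60.0,), (180.0,)],
    "CYS": [(-60.0,), (60.0,), (180.0,)],
    "THR": [(-60.0,), (60.0,), (180.0,)],
    "VAL": [(180.0,), (-60.0,), (60.0,)],
    "ILE": [(-60.0, 170.0), (180.0, 170.0), (60.0, 170.0)],
    "LEU": [(-60.0, 175.0), (180.0, 65.0), (60.0, 175.0)],
    "PRO": [(30.0, -35.0), (-30.0, 35.0)],
    "MET": [(-60.0, 180.0, 75.0), (180.0, 180.0, 75.0), (60.0, 180.0, -75.0)],
    "PHE": [(-60.0, 90.0), (180.0, 80.0), (60.0, 90.0)],
    "TYR": [(-60.0, 90.0), (180.0, 80.0), (60.0, 90.0)],
    "TRP": [(-60.0, 95.0), (180.0, -105.0), (60.0, 90.0)],
    "ASP": [(-60.0, -15.0), (180.0, 15.0), (60.0, -15.0)],
    "ASN": [(-60.0, -20.0), (180.0, 30.0), (60.0, -20.0)],
    "GLU": [(-60.0, 180.0, -10.0), (180.0, 180.0, 0.0), (60.0, 180.0, -10.0)],
    "GLN": [(-60.0, 180.0, 60.0), (180.0, 180.0, 0.0), (60.0, 180.0, 60.0)],
    "LYS": [(-60.0, 180.0, 180.0, 180.0), (180.0, 180.0, 180.0, 180.0),
            (60.0, 180.0, 180.0, 180.0)],
    "ARG": [(-60.0, 180.0, 180.0, 180.0), (180.0, 180.0, 180.0, 180.0),
            (60.0, 180.0, 180.0, 180.0)],
    "HIS": [(-60.0, -75.0), (180.0, -75.0), (60.0, 75.0)],
    "ALA": [()],
    "GLY": [()],
}

# Chou-Fasman secondary-structure propensities (helix, strand); coil filled
# as the complement so each residue's three priors sum to ~3.
CHOU_FASMAN = {
    "A": (1.42, 0.83), "R": (0.98, 0.93), "N": (0.67, 0.89), "D": (1.01, 0.54),
    "C": (0.70, 1.19), "Q": (1.11, 1.10), "E": (1.51, 0.37), "G": (0.57, 0.75),
    "H": (1.00, 0.87), "I": (1.08, 1.60), "L": (1.21, 1.30), "K": (1.16, 0.74),
    "M": (1.45, 1.05), "F": (1.13, 1.38), "P": (0.57, 0.55), "S": (0.77, 0.75),
    "T": (0.83, 1.19), "W": (1.08, 1.37), "Y": (0.69, 1.47), "V": (1.06, 1.70),
}

# gamma-annotation classes
GAMMA_CLASSES = ("GLY", "PSEUDO_SER", "PRO", "BRANCHED", "UNKNOWN")

# P(annotation class | residue type): rows = class, columns = AMINO_ACIDS.
# Constructed compatibility table: a GLY annotation (no beta density)
# penalises large side chains; BRANCHED favours V/T/I; PRO favours proline;
# PSEUDO_SER is the broad single-gamma class; UNKNOWN is uninformative.
def _density_table() -> dict[str, dict[str, float]]:
    base = {}
    single_gamma = set("SCDENQHKRLMFWYI")  # one dominant chi1 direction
    branched = set("VTI")
    for cls in GAMMA_CLASSES:
        row = {}
        for aa in AMINO_ACIDS:
            if cls == "GLY":
                p = 0.70 if aa == "G" else (0.15 if aa in "ASC" else 0.03)
            elif cls == "BRANCHED":
                p = 0.70 if aa in branched else (0.08 if aa in single_gamma else 0.02)
            elif cls == "PRO":
                p = 0.65 if aa == "P" else (0.06 if aa in single_gamma else 0.03)
            elif cls == "PSEUDO_SER":
                p = 0.40 if aa in single_gamma else (0.15 if aa in branched else 0.04)
            else:  # UNKNOWN
                p = 1.0
            row[aa] = p
        total = sum(row.values())
        base[cls] = {aa: v / total for aa, v in row.items()}
    return base


P_DENSITY = _density_table()


def secondary_structure_priors() -> dict[str, dict[str, float]]:
    """P(type | secondary-structure label) from Chou-Fasman propensities."""
    out = {}
    for label in ("H", "E", "C"):
        row = {}
        for aa in AMINO_ACIDS:
            ph, pe = CHOU_FASMAN[aa]
            if label == "H":
                row[aa] = ph
            elif label == "E":
                row[aa] = pe
            else:
                row[aa] = max(3.0 - ph - pe, 0.05)
        total = sum(row.values())
        out[label] = {aa: v / total for aa, v in row.items()}
    return out


SS_PRIORS = secondary_structure_priors()


def ramachandran_allowed(phi: float, psi: float) -> bool:
    """Coarse, generous allowed mask (favoured + allowed regions).

    Union of boxes around the alpha, beta and left-handed-alpha basins;
    pruning is intentionally conservative since removal also requires weak
    density.
    """
    phi = (phi + 180.0) % 360.0 - 180.0
    psi = (psi + 180.0) % 360.0 - 180.0
    if -170.0 <= phi <= -30.0 and -90.0 <= psi <= 60.0:
        return True  # alpha basin
    if -180.0 <= phi <= -40.0 and (psi >= 80.0 or psi <= -150.0):
        return True  # beta / PPII basin (psi wraps at 180)
    if 20.0 <= phi <= 100.0 and -10.0 <= psi <= 100.0:
        return True  # left-handed alpha
    return False
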