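"""Polyalanine traces: ordered chains of residues with backbone atoms."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import dihedral, place_cb
from .model import AtomicModel
from .symmetry import UnitCell

__all__ = ["Residue", "Trace"]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
CA_CA_MIN, CA_CA_MAX = 2.7, 4.3  # cis/trans envelope


@dataclass
class Residue:
    """One residue: atom-name -> orthogonal position; optional annotation."""

    atoms: dict[str, np.ndarray]
    name: str = "ALA"
    annotation: object = None

    def __post_init__(self):
        self.atoms = {k: np.asarray(v, dtype=float) for k, v in self.atoms.items()}
        for a in ("N", "CA", "C"):
            if a not in self.atoms:
                raise ValueError(f"residue missing backbone atom {a}")

    def copy(self) -> "Residue":
        return Residue({k: v.copy() for k, v in self.atoms.items()}, self.name, self.annotation)

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]

    def backbone_positions(self) -> np.ndarray:
        return np.array([self.atoms[a] for a in BACKBONE_ATOMS if a in self.atoms])

    def ensure_cb(self) -> np.ndarray:
        if "CB" not in self.atoms:
            self.atoms["CB"] = place_cb(self.atoms["N"], self.atoms["CA"], self.atoms["C"])
        return self.atoms["CB"]


@dataclass
class Trace:
    """Ordered chains of residues (orthogonal coordinates).

    ``validate=False`` skips the CA-CA envelope check, for deliberately
    defective traces (e.g. error-correction fixtures).
    """

    chains: list[list[Residue]] = field(default_factory=list)
    validate_geometry: bool = True

    def __post_init__(self):
        if self.validate_geometry:
            self.validate()

    def validate(self):
        for chain in self.chains:
            cas = np.array([r.ca for r in chain])
            if len(cas) > 1:
                d = np.linalg.norm(np.diff(cas, axis=0), axis=1)
                if np.any((d < CA_CA_MIN) | (d > CA_CA_MAX)):
                    bad = np.where((d < CA_CA_MIN) | (d > CA_CA_MAX))[0]
                    raise ValueError(
                        f"CA-CA distance outside [{CA_CA_MIN}, {CA_CA_MAX}] A at "
                        f"connection {bad[0]}"
                    )

    def copy(self) -> "Trace":
        return Trace(
            [[r.copy() for r in chain] for chain in self.chains],
            validate_geometry=self.validate_geometry,
        )

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def __len__(self):
        return len(self.chains)

    def phi_psi(self, chain_idx: int):
        """(phi, psi) per residue of a chain; NaN at the termini."""
        chain = self.chains[chain_idx]
        n = len(chain)
        phi = np.full(n, np.nan)
        psi = np.full(n, np.nan)
        for i, res in enumerate(chain):
            if i > 0:
                phi[i] = dihedral(
                    chain[i - 1].atoms["C"], res.atoms["N"], res.atoms["CA"], res.atoms["C"]
                )
            if i + 1 < n:
                psi[i] = dihedral(
                    res.atoms["N"], res.atoms["CA"], res.atoms["C"], chain[i + 1].atoms["N"]
                )
        return phi, psi

    def to_model(
        self,
        cell: UnitCell,
        polyalanine: bool = True,
        b_factor: float = 20.0,
    ) -> AtomicModel:
        """Convert to an AtomicModel (backbone + CB unless residue is GLY).

        With ``polyalanine=False``, all stored side-chain atoms are kept.
        """
        elements, names, xyz, resname, resseq, chain_ids, occ = [], [], [], [], [], [], []
        seq = 0
        for ci, chain in enumerate(self.chains):
            cid = chr(ord("A") + (ci % 26))
            for res in chain:
                seq += 1
                keep = list(BACKBONE_ATOMS)
                if res.name != "GLY":
                    res.ensure_cb()
                    keep.append("CB")
                if not polyalanine:
                    keep += [a for a in res.atoms if a not in keep]
                for a in keep:
                    if a not in res.atoms:
                        continue
                    elements.append("N" if a.startswith("N") else
                                    "O" if a.startswith("O") else
                                    "S" if a.startswith("S") and a != "SE" else
                                    "SE" if a.startswith("SE") else "C")
                    names.append(a)
                    xyz.append(res.atoms[a])
                    resname.append(res.name if not polyalanine else
                                   ("GLY" if res.name == "GLY" else "ALA"))
                    resseq.append(seq)
                    chain_ids.append(cid)
                    occ.append(1.0)
        return AtomicModel.from_orthogonal(
            np.array(elements, dtype=object),
            np.array(xyz),
            cell,
            occ=np.array(occ),
            b=np.full(len(xyz), b_factor),
            name=np.array(names, dtype=object),
            resname=np.array(resname, dtype=object),
            resseq=np.array(resseq),
            chain=np.array(chain_ids, dtype=object),
        )
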