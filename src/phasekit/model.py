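"""Atomic models: columnar atom storage with residue/chain bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formfactors import normalize_element
from .symmetry import UnitCell

__all__ = ["AtomicModel"]


@dataclass
class AtomicModel:
    """A list of scatterers in fractional coordinates.

    Parameters are columnar numpy arrays; ``name``/``resname``/``resseq``/
    ``chain`` carry protein bookkeeping and may be left at their defaults
    for bare scatterer lists (e.g. substructure sites).
    """

    elements: np.ndarray  # str per atom
    xyz_frac: np.ndarray  # (N, 3)
    occ: np.ndarray | None = None
    b: np.ndarray | None = None
    name: np.ndarray | None = None
    resname: np.ndarray | None = None
    resseq: np.ndarray | None = None
    chain: np.ndarray | None = None

    def __post_init__(self):
        self.xyz_frac = np.atleast_2d(np.asarray(self.xyz_frac, dtype=float))
        n = len(self.xyz_frac)
        self.elements = np.asarray(
            [normalize_element(e) for e in np.atleast_1d(self.elements)], dtype=object
        )
        if self.occ is None:
            self.occ = np.ones(n)
        self.occ = np.asarray(self.occ, dtype=float)
        if self.b is None:
            self.b = np.full(n, 15.0)
        self.b = np.asarray(self.b, dtype=float)
        if np.any((self.occ < 0) | (self.occ > 1)):
            raise ValueError("occupancies must lie in [0, 1]")
        if np.any(self.b <= 0):
            raise ValueError("isotropic B must be positive")
        if self.name is None:
            self.name = np.asarray(self.elements, dtype=object)
        if self.resname is None:
            self.resname = np.asarray(["UNK"] * n, dtype=object)
        if self.resseq is None:
            self.resseq = np.arange(1, n + 1)
        if self.chain is None:
            self.chain = np.asarray(["A"] * n, dtype=object)
        self.name = np.asarray(self.name, dtype=object)
        self.resname = np.asarray(self.resname, dtype=object)
        self.resseq = np.asarray(self.resseq, dtype=int)
        self.chain = np.asarray(self.chain, dtype=object)

    def __len__(self):
        return len(self.xyz_frac)

    @classmethod
    def from_orthogonal(cls, elements, xyz_orth, cell: UnitCell, **kw) -> "AtomicModel":
        return cls(elements, cell.fractionalize(np.asarray(xyz_orth)), **kw)

    def xyz_orth(self, cell: UnitCell) -> np.ndarray:
        return cell.orthogonalize(self.xyz_frac)

    def copy(self) -> "AtomicModel":
        return AtomicModel(
            self.elements.copy(),
            self.xyz_frac.copy(),
            self.occ.copy(),
            self.b.copy(),
            self.name.copy(),
            self.resname.copy(),
            self.resseq.copy(),
            self.chain.copy(),
        )

    def select(self, mask) -> "AtomicModel":
        return AtomicModel(
            self.elements[mask],
            self.xyz_frac[mask],
            self.occ[mask],
            self.b[mask],
            self.name[mask],
            self.resname[mask],
            self.resseq[mask],
            self.chain[mask],
        )

    @staticmethod
    def concatenate(models: list["AtomicModel"]) -> "AtomicModel":
        models = [m for m in models if len(m)]
        if not models:
            raise ValueError("nothing to concatenate")
        return AtomicModel(
            np.concatenate([m.elements for m in models]),
            np.concatenate([m.xyz_frac for m in models]),
            np.concatenate([m.occ for m in models]),
            np.concatenate([m.b for m in models]),
            np.concatenate([m.name for m in models]),
            np.concatenate([m.resname for m in models]),
            np.concatenate([m.resseq for m in models]),
            np.concatenate([m.chain for m in models]),
        )

    def with_scaled_occupancy(self, factor: float) -> "AtomicModel":
        out = self.copy()
        out.occ = np.clip(out.occ * factor, 0.0, 1.0)
        return out
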