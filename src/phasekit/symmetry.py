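"""Unit cells and a minimal space-group set.

Supported groups are P1, P2(1), P2(1)2(1)2(1) and P4(3)2(1)2 — enough to
exercise triclinic, monoclinic (polar axis), primitive orthorhombic and a
tetragonal enantiomorphic group.  Operator triplets come from gemmi's
space-group tables; the allowed-origin-shift data needed for phase-set
reconciliation are derived here from the operators themselves.

Conventions
-----------
Symmetry operators act on fractional column vectors, x' = R x + t.  The
equivalent reflection index is h' = R^T h with the phase relation
phi(h') = phi(h) - 360 (h . t).  All angles are degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product

import gemmi
import numpy as np

__all__ = ["UnitCell", "SpaceGroup", "SUPPORTED_SPACEGROUPS"]

# canonical symbol -> (gemmi Hermann-Mauguin name, enantiomorph partner or None)
SUPPORTED_SPACEGROUPS = {
    "P1": ("P 1", None),
    "P21": ("P 1 21 1", None),
    "P212121": ("P 21 21 21", None),
    "P43212": ("P 43 21 2", "P41212"),
}


@dataclass(frozen=True)
class UnitCell:
    """Crystal unit cell; lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        for L in (self.a, self.b, self.c):
            if L <= 0:
                raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180)")
        if np.linalg.det(self.metric_tensor()) <= 0:
            raise ValueError("cell metric tensor is not positive definite")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    def metric_tensor(self) -> np.ndarray:
        """Real-space metric tensor G (Angstrom^2)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    @property
    def volume(self) -> float:
        return float(np.sqrt(np.linalg.det(self.metric_tensor())))

    def orthogonalization_matrix(self) -> np.ndarray:
        """Standard PDB convention: a along x, b in the x-y plane."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.radians(self.gamma))
        v = self.volume
        return np.array(
            [
                [a, b * cg, c * cb],
                [0.0, b * sg, c * (ca - cb * cg) / sg],
                [0.0, 0.0, v / (a * b * sg)],
            ]
        )

    def fractionalization_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization_matrix())

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        """Fractional -> orthogonal Angstrom (positions in rows)."""
        return np.asarray(frac) @ self.orthogonalization_matrix().T

    def fractionalize(self, orth: np.ndarray) -> np.ndarray:
        return np.asarray(orth) @ self.fractionalization_matrix().T

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Angstrom) of reflections; hkl shape (..., 3)."""
        g_star = np.linalg.inv(self.metric_tensor())
        h = np.asarray(hkl, dtype=float)
        inv_d2 = np.einsum("...i,ij,...j->...", h, g_star, h)
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(inv_d2)


def _frac_vec(vals) -> np.ndarray:
    return np.array([float(Fraction(v).limit_denominator(24)) for v in vals])


class SpaceGroup:
    """A space group as rotation/translation operator pairs.

    Parameters
    ----------
    symbol : str
        One of ``P1``, ``P21``, ``P212121``, ``P43212``.

    Attributes
    ----------
    operators : list of (R, t)
        Integer 3x3 rotation parts and fractional translations, acting on
        fractional column vectors.
    polar_axes : ndarray of bool, shape (3,)
        Axes along which the origin floats freely.
    origin_shifts : ndarray, shape (n, 3)
        Discrete allowed origin shifts (polar components set to 0).
    inversion_points : ndarray, shape (m, 3)
        Fractional points through which inversion maps the structure onto an
        equivalent (possibly enantiomorphic) description.
    enantiomorph : str or None
        Symbol of the enantiomorphic partner group, if any.
    """

    _ALIASES = {"P1211": "P21", "P121": "P21", "P1121": "P21"}

    def __init__(self, symbol: str):
        key = symbol.replace(" ", "").replace("_", "").upper()
        key = self._ALIASES.get(key, key)
        if key not in SUPPORTED_SPACEGROUPS:
            raise ValueError(
                f"unsupported space group {symbol!r}; supported: "
                + ", ".join(SUPPORTED_SPACEGROUPS)
            )
        hm, partner = SUPPORTED_SPACEGROUPS[key]
        self.symbol = key
        self.hm_symbol = hm
        self.enantiomorph = partner
        gsg = gemmi.SpaceGroup(hm)
        self.operators: list[tuple[np.ndarray, np.ndarray]] = []
        for op in gsg.operations():
            rot = np.array(op.rot, dtype=float) / op.DEN
            tran = np.array(op.tran, dtype=float) / op.DEN
            self.operators.append((rot.astype(int), tran))
        self._check_group()
        self.polar_axes, self.origin_shifts = self._allowed_origin_shifts()
        self.inversion_points = self._inversion_points()

    # -- group structure -------------------------------------------------

    def _check_group(self):
        ops = {self._op_key(r, t) for r, t in self.operators}
        ident = self._op_key(np.eye(3, dtype=int), np.zeros(3))
        if ident not in ops:
            raise AssertionError("identity operator missing")
        for r1, t1 in self.operators:
            for r2, t2 in self.operators:
                r = r1 @ r2
                t = (r1 @ t2 + t1) % 1.0
                if self._op_key(r, t) not in ops:
                    raise AssertionError("operators not closed under composition")

    @staticmethod
    def _op_key(r, t):
        return (tuple(np.asarray(r, dtype=int).ravel()), tuple(np.round(np.asarray(t) % 1.0, 6)))

    def __len__(self):
        return len(self.operators)

    def __repr__(self):
        return f"SpaceGroup({self.symbol!r}, {len(self)} operators)"

    # -- origin data ------------------------------------------------------

    def _allowed_origin_shifts(self):
        # A shift t of the origin is allowed iff (R - I) t is a lattice
        # vector for every operator: the operator set is then unchanged.
        mats = [r - np.eye(3, dtype=int) for r, _ in self.operators]
        # polar directions: common integer null space along the axes
        polar = np.array(
            [all(np.allclose(m[:, k], 0) for m in mats) for k in range(3)]
        )
        shifts = []
        grid = [0.0, 0.25, 0.5, 0.75]
        for t in product(grid, grid, grid):
            t = np.array(t)
            if np.any(t[polar] != 0.0):
                continue  # polar components handled continuously
            ok = all(np.allclose((m @ t) % 1.0, np.round((m @ t) % 1.0)) for m in mats)
            if ok:
                shifts.append(t)
        return polar, np.array(sorted(shifts, key=tuple))

    def _inversion_points(self):
        # Points p through which inversion (x -> 2p - x) maps the operator
        # set onto itself or its enantiomorph.  For the supported primitive
        # groups the standard choice p in origin-shift lattice /2 works;
        # non-origin centres (cf. I41-type groups) are representable.
        pts = [np.zeros(3)]
        for s in self.origin_shifts:
            p = s / 2.0
            if not any(np.allclose(p, q) for q in pts):
                pts.append(p)
        return np.array(pts)

    # -- reflection utilities ---------------------------------------------

    def reciprocal_orbit(self, hkl: np.ndarray):
        """Equivalent indices h' = R^T h with phase shifts -360 h.t (degrees)."""
        h = np.asarray(hkl)
        out = []
        for r, t in self.operators:
            out.append((r.T @ h, -360.0 * float(h @ t)))
        return out

    def is_centric(self, hkl: np.ndarray) -> np.ndarray:
        """Centric flag per reflection: some operator maps h to -h."""
        h = np.atleast_2d(np.asarray(hkl, dtype=int))
        flags = np.zeros(len(h), dtype=bool)
        for r, _ in self.operators:
            flags |= np.all(h @ r == -h, axis=1)
        return flags

    def is_absent(self, hkl: np.ndarray) -> np.ndarray:
        """Systematic absence: some op with h R = h has non-integral h.t."""
        h = np.atleast_2d(np.asarray(hkl, dtype=int))
        absent = np.zeros(len(h), dtype=bool)
        for r, t in self.operators:
            fixed = np.all(h @ r == h, axis=1)
            phase = h @ t
            absent |= fixed & (np.abs(phase - np.round(phase)) > 1e-9)
        return absent
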