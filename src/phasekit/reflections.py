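"""Reflection lists: indices, amplitudes, phases, figures of merit, HL coefficients.

The asymmetric-unit convention stores one representative per symmetry orbit
(including Friedel mates), chosen in the hemisphere l > 0, or l = 0 and
k > 0, or l = k = 0 and h >= 0, tie-broken lexicographically (largest
(h, k, l) tuple wins).  Phases follow the map convention
rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .symmetry import SpaceGroup, UnitCell

__all__ = ["ReflectionSet", "unique_hkl", "reduce_to_asu"]


def _in_hemisphere(hkl: np.ndarray) -> np.ndarray:
    h, k, l = hkl[..., 0], hkl[..., 1], hkl[..., 2]
    return (l > 0) | ((l == 0) & (k > 0)) | ((l == 0) & (k == 0) & (h >= 0))


def reduce_to_asu(hkl: np.ndarray, sg: SpaceGroup):
    """Map each reflection to its asymmetric-unit representative.

    Returns ``(rep_hkl, sign, shift_deg)`` such that
    ``phi_rep = sign * phi + shift_deg`` (mod 360).
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    n = len(hkl)
    best = None
    for r, t in sg.operators:
        h2 = hkl @ r  # h' = R^T h
        shift = -360.0 * (hkl @ t)
        for cand, sign, sh in ((h2, 1.0, shift), (-h2, -1.0, -shift)):
            hemi = _in_hemisphere(cand)
            # lexicographic key; out-of-hemisphere candidates rank last
            key = np.stack(
                [np.where(hemi, 1.0, -1.0), cand[:, 0], cand[:, 1], cand[:, 2]], axis=1
            )
            if best is None:
                best = (cand.copy(), np.full(n, sign), sh.copy(), key)
                continue
            better = _lex_greater(key, best[3])
            bh, bs, bsh, bk = best
            bh[better] = cand[better]
            bs[better] = sign
            bsh[better] = sh[better]
            bk[better] = key[better]
    rep, sign, shift, _ = best
    return rep, sign, shift % 360.0


def _lex_greater(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise lexicographic a > b."""
    out = np.zeros(len(a), dtype=bool)
    undecided = np.ones(len(a), dtype=bool)
    for j in range(a.shape[1]):
        gt = undecided & (a[:, j] > b[:, j])
        lt = undecided & (a[:, j] < b[:, j])
        out |= gt
        undecided &= ~(gt | lt)
    return out


def unique_hkl(cell: UnitCell, sg: SpaceGroup, d_min: float) -> np.ndarray:
    """All unique, present reflections to resolution d_min, sorted."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    g_star = np.linalg.inv(cell.metric_tensor())
    hmax = np.floor(1.0 / (d_min * np.sqrt(np.diag(g_star)))).astype(int)
    axes = [np.arange(-m, m + 1) for m in hmax]
    hh, kk, ll = np.meshgrid(*axes, indexing="ij")
    hkl = np.stack([hh.ravel(), kk.ravel(), ll.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = cell.d_spacing(hkl)
    hkl = hkl[d >= d_min]
    rep, _, _ = reduce_to_asu(hkl, sg)
    rep = np.unique(rep, axis=0)
    rep = rep[~sg.is_absent(rep)]
    order = np.lexsort((rep[:, 2], rep[:, 1], rep[:, 0]))
    return rep[order]


@dataclass
class ReflectionSet:
    """Indexed structure-factor list (one row per unique reflection).

    ``phi`` and ``fom`` are NaN where absent; ``hl`` is an (N, 4) array of
    Hendrickson-Lattman coefficients or None; ``measured`` distinguishes
    observed amplitudes from extrapolated ones.
    """

    hkl: np.ndarray
    F: np.ndarray
    sigF: np.ndarray | None = None
    phi: np.ndarray | None = None
    fom: np.ndarray | None = None
    hl: np.ndarray | None = None
    measured: np.ndarray | None = None
    cell: UnitCell | None = None
    spacegroup: SpaceGroup | None = None

    def __post_init__(self):
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=int))
        n = len(self.hkl)
        self.F = np.asarray(self.F, dtype=float)
        if self.sigF is None:
            self.sigF = np.zeros(n)
        self.sigF = np.asarray(self.sigF, dtype=float)
        self.phi = (
            np.full(n, np.nan) if self.phi is None else np.asarray(self.phi, dtype=float)
        )
        self.fom = (
            np.full(n, np.nan) if self.fom is None else np.asarray(self.fom, dtype=float)
        )
        if self.hl is not None:
            self.hl = np.asarray(self.hl, dtype=float).reshape(n, 4)
        if self.measured is None:
            self.measured = np.ones(n, dtype=bool)
        self.measured = np.asarray(self.measured, dtype=bool)
        if len(np.unique(self.hkl, axis=0)) != n:
            raise ValueError("duplicate reflection indices")
        ok = np.isnan(self.fom) | ((self.fom >= 0) & (self.fom <= 1))
        if not np.all(ok):
            raise ValueError("figures of merit must lie in [0, 1]")

    def __len__(self):
        return len(self.hkl)

    @property
    def d(self) -> np.ndarray:
        if self.cell is None:
            raise ValueError("no unit cell attached")
        return self.cell.d_spacing(self.hkl)

    @property
    def has_phases(self) -> np.ndarray:
        return ~np.isnan(self.phi)

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(
            self.hkl.copy(),
            self.F.copy(),
            self.sigF.copy(),
            self.phi.copy(),
            self.fom.copy(),
            None if self.hl is None else self.hl.copy(),
            self.measured.copy(),
            self.cell,
            self.spacegroup,
        )

    def select(self, mask: np.ndarray) -> "ReflectionSet":
        return ReflectionSet(
            self.hkl[mask],
            self.F[mask],
            self.sigF[mask],
            self.phi[mask],
            self.fom[mask],
            None if self.hl is None else self.hl[mask],
            self.measured[mask],
            self.cell,
            self.spacegroup,
        )

    def sort(self) -> "ReflectionSet":
        order = np.lexsort((self.hkl[:, 2], self.hkl[:, 1], self.hkl[:, 0]))
        return self.select(order)

    def index_map(self) -> dict[tuple[int, int, int], int]:
        return {tuple(h): i for i, h in enumerate(self.hkl)}

    def match(self, other: "ReflectionSet"):
        """Indices (i_self, i_other) of common reflections."""
        lut = other.index_map()
        pairs = [
            (i, lut[tuple(h)]) for i, h in enumerate(self.hkl) if tuple(h) in lut
        ]
        if not pairs:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        a, b = zip(*pairs)
        return np.array(a), np.array(b)
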