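"""Electron-density maps: FFT synthesis, inversion and interpolation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fftn, ifftn, next_fast_len

from .reflections import ReflectionSet, unique_hkl
from .symmetry import SpaceGroup, UnitCell

__all__ = ["DensityMap", "grid_for_resolution", "map_from_phases", "invert_map", "interpolate_density"]


def grid_for_resolution(cell: UnitCell, d_min: float, oversampling: float = 4.0):
    """FFT-friendly grid with spacing <= d_min / oversampling on each axis.

    Dimensions are multiples of 4 so that the 1/2 and 1/4 translations of
    the supported screw axes map the grid onto itself exactly.
    """
    if oversampling < 3.0:
        raise ValueError("grid oversampling below 3 points per d_min is too coarse")
    dims = []
    for length in cell.lengths:
        n = 4 * int(np.ceil(length * oversampling / d_min / 4.0))
        while next_fast_len(n) != n:
            n += 4
        dims.append(n)
    return tuple(dims)


@dataclass
class DensityMap:
    """Real-space density on a periodic grid over the unit cell."""

    values: np.ndarray
    cell: UnitCell
    spacegroup: SpaceGroup | None = None
    d_min: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("map grid must be 3-D with >= 2 points per axis")

    @property
    def shape(self):
        return self.values.shape

    @property
    def sigma(self) -> float:
        return float(np.std(self.values))

    def spacing(self) -> np.ndarray:
        return self.cell.lengths / np.array(self.shape)

    def copy(self) -> "DensityMap":
        return DensityMap(self.values.copy(), self.cell, self.spacegroup, self.d_min)


def _expand_to_p1(refl: ReflectionSet, sg: SpaceGroup):
    """All symmetry- and Friedel-equivalent (hkl, complex F) pairs."""
    use = refl.has_phases & np.isfinite(refl.F)
    hkl = refl.hkl[use]
    fom = np.where(np.isnan(refl.fom[use]), 1.0, refl.fom[use])
    coef = fom * refl.F[use] * np.exp(1j * np.radians(refl.phi[use]))
    all_h, all_c = [], []
    for r, t in sg.operators:
        h2 = hkl @ r
        shift = np.exp(-2j * np.pi * (hkl @ t))
        all_h.append(h2)
        all_c.append(coef * shift)
        all_h.append(-h2)
        all_c.append(np.conj(coef * shift))
    return np.concatenate(all_h), np.concatenate(all_c)


def map_from_phases(
    refl: ReflectionSet,
    cell: UnitCell | None = None,
    sg: SpaceGroup | None = None,
    grid=None,
    d_min: float | None = None,
    oversampling: float = 4.0,
) -> DensityMap:
    """Inverse-FFT map synthesis with m*F coefficients (m = 1 where absent)."""
    cell = cell or refl.cell
    sg = sg or refl.spacegroup
    if cell is None or sg is None:
        raise ValueError("cell and space group required")
    if d_min is None:
        used = refl.has_phases
        d_min = float(np.min(cell.d_spacing(refl.hkl[used]))) if used.any() else 2.0
    if grid is None:
        grid = grid_for_resolution(cell, d_min, oversampling)
    n = np.array(grid)

    hfull, cfull = _expand_to_p1(refl, sg)
    if np.any(2 * np.abs(hfull) >= n[None, :]):
        raise ValueError("grid too coarse for the resolution of the data")
    idx = np.ravel_multi_index((hfull % n).T, grid)
    # one deposit per unique index (equivalents carry identical values)
    _, first = np.unique(idx, return_index=True)
    g = np.zeros(grid, dtype=complex)
    g.flat[idx[first]] = cfull[first]
    rho = np.real(fftn(g)) / cell.volume
    return DensityMap(rho, cell, sg, d_min=d_min)


def invert_map(
    dmap: DensityMap, d_min: float, hkl: np.ndarray | None = None
) -> ReflectionSet:
    """Forward FFT; amplitudes and phases for unique reflections to d_min."""
    cell, sg = dmap.cell, dmap.spacegroup or SpaceGroup("P1")
    if hkl is None:
        hkl = unique_hkl(cell, sg, d_min)
    n = np.array(dmap.shape)
    if np.any(2 * np.abs(hkl) >= n[None, :]):
        raise ValueError("grid too coarse for requested resolution")
    coeffs = ifftn(dmap.values) * cell.volume
    f = coeffs[tuple((hkl % n).T)]
    return ReflectionSet(
        hkl,
        F=np.abs(f),
        phi=np.degrees(np.angle(f)) % 360.0,
        fom=np.ones(len(hkl)),
        measured=np.zeros(len(hkl), dtype=bool),  # calculated, not observed
        cell=cell,
        spacegroup=sg,
    )


def interpolate_density(
    dmap: DensityMap, positions_orth: np.ndarray, order: int = 3
) -> np.ndarray:
    """Interpolated density at orthogonal-Angstrom positions (wrapped).

    Cubic-spline interpolation on the periodic grid by default (``order=1``
    falls back to trilinear); at 4 points per d_min the cubic error is well
    below a percent of the map sigma.
    """
    from scipy.ndimage import map_coordinates

    pos = np.atleast_2d(np.asarray(positions_orth, dtype=float))
    frac = dmap.cell.fractionalize(pos) % 1.0
    coords = (frac * np.array(dmap.shape)).T
    vals = map_coordinates(dmap.values, coords, order=order, mode="grid-wrap")
    if np.ndim(positions_orth) == 1:
        return float(vals[0])
    return vals
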