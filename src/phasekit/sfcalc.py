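"""Structure factors by direct summation over symmetry-expanded atoms.

F(h) = sum_j f_j(s) occ_j exp(-B_j s^2) exp(+2 pi i h.x_j),  s = 1/(2 d),
consistent with the map convention rho(x) = (1/V) sum F(h) exp(-2 pi i h.x).
"""

from __future__ import annotations

import numpy as np

from .formfactors import scattering_factor
from .model import AtomicModel
from .reflections import ReflectionSet, unique_hkl
from .symmetry import SpaceGroup, UnitCell

__all__ = ["compute_structure_factors", "structure_factor_amplitudes"]


def compute_structure_factors(
    model: AtomicModel,
    cell: UnitCell,
    sg: SpaceGroup,
    d_min: float,
    hkl: np.ndarray | None = None,
) -> ReflectionSet:
    """Direct-summation F, phi for every unique reflection to ``d_min``."""
    if len(model) == 0:
        raise ValueError("model is empty")
    if hkl is None:
        hkl = unique_hkl(cell, sg, d_min)
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    d = cell.d_spacing(hkl)
    s2 = 1.0 / (4.0 * d**2)

    # symmetry-expand atom positions
    pos = np.concatenate(
        [(model.xyz_frac @ r.T + t) for r, t in sg.operators], axis=0
    )
    occ = np.tile(model.occ, len(sg.operators))
    b = np.tile(model.b, len(sg.operators))
    elements = np.tile(model.elements, len(sg.operators))

    fcalc = np.zeros(len(hkl), dtype=complex)
    for el in np.unique(elements.astype(str)):
        sel = elements == el
        f_el = scattering_factor(el, s2)  # (n_hkl,)
        phase = np.exp(2j * np.pi * (hkl @ pos[sel].T))  # (n_hkl, M)
        attn = occ[sel][None, :] * np.exp(-np.outer(s2, b[sel]))
        fcalc += f_el * np.sum(phase * attn, axis=1)

    return ReflectionSet(
        hkl,
        F=np.abs(fcalc),
        phi=np.degrees(np.angle(fcalc)) % 360.0,
        fom=np.ones(len(hkl)),
        cell=cell,
        spacegroup=sg,
    )


def structure_factor_amplitudes(model, cell, sg, hkl) -> np.ndarray:
    """|Fcalc| on a given index list (convenience for CC computations)."""
    return compute_structure_factors(model, cell, sg, d_min=1e-6, hkl=hkl).F
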