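"""Phase-error and amplitude-agreement statistics.

MPE is the mean minimal absolute phase difference (degrees, 90 is the
random expectation); wMPE weights each reflection by the reference figure
of merit.  Centric reflections (phase restricted by symmetry) are reported
separately.  ``reconcile_phases`` removes the space-group origin-shift and
enantiomorph ambiguity before two phase sets are compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.optimize import minimize

from .model import AtomicModel
from .reflections import ReflectionSet
from .sfcalc import compute_structure_factors
from .symmetry import SpaceGroup, UnitCell

__all__ = ["PhaseComparison", "phase_error", "reconcile_phases", "cc_fo_fc"]


@dataclass
class PhaseComparison:
    """Per-reflection phase differences plus their weighted summaries."""

    hkl: np.ndarray
    delta_phi: np.ndarray  # degrees in [0, 180]
    weight: np.ndarray
    centric: np.ndarray
    mpe: float
    wmpe: float
    mpe_centric: float
    wmpe_centric: float

    def as_tuple(self):
        return self.mpe, self.wmpe, self.mpe_centric, self.wmpe_centric


def wrap_angle(delta_deg: np.ndarray) -> np.ndarray:
    """Minimal absolute phase difference in degrees, in [0, 180]."""
    return np.abs((np.asarray(delta_deg) + 180.0) % 360.0 - 180.0)


def phase_error(
    test: ReflectionSet, ref: ReflectionSet, weights: np.ndarray | None = None
) -> PhaseComparison:
    """MPE / wMPE of ``test`` phases against ``ref`` (weights = ref fom)."""
    ia, ib = test.match(ref)
    ok = test.has_phases[ia] & ref.has_phases[ib]
    ia, ib = ia[ok], ib[ok]
    if len(ia) == 0:
        raise ValueError("no common phased reflections")
    dphi = wrap_angle(test.phi[ia] - ref.phi[ib])
    if weights is None:
        w = np.where(np.isnan(ref.fom[ib]), 1.0, ref.fom[ib])
    else:
        w = np.asarray(weights, dtype=float)[ib]
    sg = ref.spacegroup or test.spacegroup
    centric = (
        sg.is_centric(ref.hkl[ib]) if sg is not None else np.zeros(len(ib), dtype=bool)
    )
    mpe = float(np.mean(dphi))
    wmpe = float(np.sum(w * dphi) / np.sum(w)) if np.sum(w) > 0 else mpe
    if centric.any():
        mpe_c = float(np.mean(dphi[centric]))
        wc = w[centric]
        wmpe_c = float(np.sum(wc * dphi[centric]) / np.sum(wc)) if np.sum(wc) > 0 else mpe_c
    else:
        mpe_c, wmpe_c = float("nan"), float("nan")
    return PhaseComparison(ref.hkl[ib], dphi, w, centric, mpe, wmpe, mpe_c, wmpe_c)


def _transformed_phi(phi, hkl, shift, invert, inv_point):
    """phi -> phi - 360 h.t, then (optionally) inversion through inv_point."""
    out = phi - 360.0 * (hkl @ np.asarray(shift))
    if invert:
        out = 720.0 * (hkl @ np.asarray(inv_point)) - out
    return out % 360.0


def _wmpe_of(phi_t, test, ref, ia, ib, w):
    return float(np.sum(w * wrap_angle(phi_t[ia] - ref.phi[ib])) / np.sum(w))


def reconcile_phases(test: ReflectionSet, ref: ReflectionSet, sg: SpaceGroup):
    """Find the allowed origin shift (and inversion) minimising wMPE.

    Returns ``(best_shift, inverted_flag, transformed_test)``.  Polar axes
    are searched on a fine grid and refined continuously.
    """
    ia, ib = test.match(ref)
    ok = test.has_phases[ia] & ref.has_phases[ib]
    ia, ib = ia[ok], ib[ok]
    if len(ia) == 0:
        raise ValueError("no common phased reflections")
    w = np.where(np.isnan(ref.fom[ib]), 1.0, ref.fom[ib])
    hkl = test.hkl
    polar = sg.polar_axes

    def wmpe_for(shift, invert, inv_point):
        phi_t = _transformed_phi(test.phi, hkl, shift, invert, inv_point)
        return _wmpe_of(phi_t, test, ref, ia, ib, w)

    best = (np.zeros(3), False, np.zeros(3), wmpe_for(np.zeros(3), False, np.zeros(3)))
    polar_grid = np.linspace(0.0, 1.0, 24, endpoint=False)
    for invert in (False, True):
        inv_points = sg.inversion_points if invert else np.zeros((1, 3))
        for inv_point in inv_points:
            for base in sg.origin_shifts:
                candidates = [base]
                if polar.any():
                    axes_vals = [polar_grid if polar[k] else [base[k]] for k in range(3)]
                    candidates = [np.array(v) for v in product(*axes_vals)]
                for cand in candidates:
                    val = wmpe_for(cand, invert, inv_point)
                    if val < best[3] - 1e-12:
                        best = (cand, invert, inv_point, val)
            if polar.any():
                # refine continuous components from the best grid point
                shift0, inv0, p0, _ = best
                if inv0 == invert and np.allclose(p0, inv_point):
                    free = np.where(polar)[0]

                    def objective(x):
                        s = shift0.copy()
                        s[free] = x
                        return wmpe_for(s, invert, inv_point)

                    res = minimize(
                        objective, shift0[free], method="Nelder-Mead",
                        options={"xatol": 1e-5, "fatol": 1e-9},
                    )
                    if res.fun < best[3]:
                        s = shift0.copy()
                        s[free] = res.x % 1.0
                        best = (s, invert, inv_point, float(res.fun))
    shift, inverted, inv_point, _ = best
    out = test.copy()
    out.phi = _transformed_phi(test.phi, hkl, shift, inverted, inv_point)
    return shift, inverted, out


def cc_fo_fc(
    model: AtomicModel,
    refl: ReflectionSet,
    cell: UnitCell | None = None,
    sg: SpaceGroup | None = None,
) -> float:
    """Pearson correlation (x100) of normalised amplitudes Eobs vs |Ecalc|.

    Amplitudes are normalised by the root-mean-square amplitude of their
    resolution bin before correlating; without this, the common radial
    falloff correlates any two atomic models (a random-atom model scores
    over 50% on raw F, close to 0% on E).
    """
    if len(model) == 0:
        raise ValueError("model is empty")
    cell = cell or refl.cell
    sg = sg or refl.spacegroup
    meas = refl.measured & np.isfinite(refl.F)
    if np.sum(meas) < 10:
        raise ValueError("fewer than 10 measured reflections")
    hkl = refl.hkl[meas]
    fobs = refl.F[meas]
    fcalc = compute_structure_factors(model, cell, sg, d_min=1e-6, hkl=hkl).F
    d = cell.d_spacing(hkl)
    order = np.argsort(d)
    n_bins = max(1, min(10, len(d) // 30))
    eo = np.empty_like(fobs)
    ec = np.empty_like(fcalc)
    for idx in np.array_split(order, n_bins):
        eo[idx] = fobs[idx] / max(np.sqrt(np.mean(fobs[idx] ** 2)), 1e-12)
        ec[idx] = fcalc[idx] / max(np.sqrt(np.mean(fcalc[idx] ** 2)), 1e-12)
    return float(np.corrcoef(eo, ec)[0, 1] * 100.0)
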