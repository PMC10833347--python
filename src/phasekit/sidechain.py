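"""Map interpretation beyond the main chain.

Gamma probing classifies each traced residue from the density at its CB and
at the three staggered gamma positions 1.47 A from CB (a compromise between
the serine CB-OG and the general CB-CG distance); sequence docking slides
the target sequence (with two dummy residues of overhang on each end) along
each chain and scores log-probabilities combining the probe pattern with
secondary-structure propensities, anchored by anomalous-scatterer sequence
markers; error correction prunes connections with outlier Ramachandran
angles corroborated by weak density; a per-stretch correlation gate removes
side chains that do not improve the fit to the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .densitymod import DMConfig, combine_phases, run_dm
from .geometry import dihedral, grow_sidechain, place_atom
from .maps import DensityMap, interpolate_density, map_from_phases
from .metrics import cc_fo_fc, phase_error
from .model import AtomicModel
from .reflections import ReflectionSet
from .resdata import (
    AA1_TO_3,
    AMINO_ACIDS,
    GAMMA_CLASSES,
    P_DENSITY,
    ROTAMERS,
    SS_PRIORS,
    ramachandran_allowed,
)
from .sfcalc import compute_structure_factors
from .symmetry import SpaceGroup, UnitCell
from .trace import BACKBONE_ATOMS, Residue, Trace

__all__ = [
    "SidechainConfig",
    "GammaAnnotation",
    "MarkerSet",
    "DockResult",
    "gamma_probe",
    "annotate_trace_for_phasing",
    "residue_type_scores",
    "secondary_structure_labels",
    "dock_sequence",
    "error_correct",
    "stretch_cc_gate",
    "build_sidechains",
    "exclusion_mask",
    "run_extension",
]

GAMMA_PROBE_DISTANCE = 1.47   # A, compromise CB-OG / CB-CG
PSEUDO_SER_DISTANCE = 1.52    # A, modelled gamma-O sits slightly further out
PROLINE_PROBE_DISTANCE = 1.495
TETRAHEDRAL_ANGLE = 109.47
STAGGERED_CHI1 = (-60.0, 60.0, 180.0)
PROLINE_CHI1 = (-30.0, 30.0)


@dataclass
class SidechainConfig:
    """Thresholds of the interpretation stage (density units: map sigma)."""

    beta_presence: float = 0.5        # CB density below this -> glycine
    gamma_significance: float = 1.0   # max-min below this -> unknown
    branched_window: float = 0.25     # mid within this of max -> branched
    gamma_occupancy: float = 0.6      # partial occupancy of added gamma atoms
    dock_margin: float = 3.0          # log units, 'distinctly better'
    dock_cc_gate: float = 30.0        # % polyalanine CC before docking starts
    solved_cc: float = 25.0           # % polyalanine CC for the solved verdict
    marker_radius: float = 2.5        # A, marker-to-expected-site tolerance
    marker_bonus: float = 4.0         # log units per satisfied marker
    marker_penalty: float = 2.0       # log units per stranded marker
    exclusion_radius: float = 2.0     # A, model-bias exclusion mask
    n_interpretation_cycles: int = 3
    sequence_docking: bool = True
    max_docked_chains: int | None = None  # e.g. number of FASTA records (NCS copies)


@dataclass
class GammaAnnotation:
    """Per-residue side-chain class inferred from density probing."""

    cls: str = "UNKNOWN"
    rho_cb: float = float("nan")
    gamma_densities: tuple = ()
    chi1: float | None = None

    def __post_init__(self):
        if self.cls not in GAMMA_CLASSES:
            raise ValueError(f"unknown gamma class {self.cls!r}")
        if self.cls == "GLY" and self.gamma_densities:
            raise ValueError("glycine annotation must not carry gamma densities")
        if self.chi1 is not None:
            allowed = set(STAGGERED_CHI1) | set(PROLINE_CHI1)
            if self.chi1 not in allowed:
                raise ValueError(f"chi1 {self.chi1} outside the staggered/proline set")


@dataclass
class MarkerSet:
    """Anomalous-scatterer sites used as sequence markers."""

    positions: np.ndarray            # (n, 3) orthogonal A
    kinds: np.ndarray                # 'SE' | 'S' | other
    occupancies: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.kinds = np.asarray([str(k).upper() for k in np.atleast_1d(self.kinds)], dtype=object)
        if self.occupancies is None:
            self.occupancies = np.ones(len(self.positions))
        self.occupancies = np.asarray(self.occupancies, dtype=float)

    def __len__(self):
        return len(self.positions)


UNASSIGNED = None


@dataclass
class DockResult:
    """Sequence-register assignment per chain."""

    offsets: list            # per chain: int offset into the sequence, or None
    log_probs: list          # total log-probability of the best offset
    margins: list            # best minus runner-up (>= 0)
    residue_types: list      # per chain: list of 1-letter types ('?' for dummy overhang)
    diagnostics: list = field(default_factory=list)


def _gamma_positions(res: Residue, chis, bond: float) -> dict[float, np.ndarray]:
    res.ensure_cb()
    out = {}
    for chi in chis:
        out[chi] = place_atom(
            res.atoms["N"], res.atoms["CA"], res.atoms["CB"],
            bond, TETRAHEDRAL_ANGLE, chi,
        )
    return out


def _mask_lookup(mask: np.ndarray | None, dmap: DensityMap, pos: np.ndarray) -> bool:
    if mask is None:
        return False
    n = np.array(dmap.shape)
    frac = dmap.cell.fractionalize(pos) % 1.0
    idx = tuple((np.floor(frac * n).astype(int) % n))
    return bool(mask[idx])


def gamma_probe(
    trace: Trace,
    dmap: DensityMap,
    cfg: SidechainConfig | None = None,
    mask: np.ndarray | None = None,
) -> list[list[GammaAnnotation]]:
    """Classify every residue from the density around its beta/gamma sites.

    ``mask`` (optional per-voxel boolean, see :func:`exclusion_mask`) makes
    residues whose CB falls in a masked voxel ineligible: they come back
    UNKNOWN.  Returns one annotation list per chain.
    """
    cfg = cfg or SidechainConfig()
    sigma = dmap.sigma
    featureless = sigma <= 1e-12
    out = []
    for chain in trace.chains:
        anns = []
        for res in chain:
            cb = res.ensure_cb()
            if featureless or _mask_lookup(mask, dmap, cb):
                anns.append(GammaAnnotation("UNKNOWN"))
                continue
            rho_cb = interpolate_density(dmap, cb)
            if rho_cb < cfg.beta_presence * sigma:
                anns.append(GammaAnnotation("GLY", rho_cb=rho_cb))
                continue
            gpos = _gamma_positions(res, STAGGERED_CHI1, GAMMA_PROBE_DISTANCE)
            rhos = {chi: interpolate_density(dmap, p) for chi, p in gpos.items()}
            vals = np.array([rhos[c] for c in STAGGERED_CHI1])
            r_sorted = np.sort(vals)[::-1]
            r_max, r_mid, r_min = r_sorted
            if (r_max - r_min) < cfg.gamma_significance * sigma:
                anns.append(GammaAnnotation("UNKNOWN", rho_cb=rho_cb,
                                            gamma_densities=tuple(vals)))
                continue
            best_chi = STAGGERED_CHI1[int(np.argmax(vals))]
            if best_chi != 180.0:
                # non-trans maximum: try the proline-specific +-30 deg probe
                ppos = _gamma_positions(res, PROLINE_CHI1, PROLINE_PROBE_DISTANCE)
                prho = {chi: interpolate_density(dmap, p) for chi, p in ppos.items()}
                p_best = max(prho, key=prho.get)
                if prho[p_best] > r_max:
                    anns.append(GammaAnnotation("PRO", rho_cb=rho_cb,
                                                gamma_densities=tuple(vals),
                                                chi1=p_best))
                    continue
            if (r_max - r_mid) <= cfg.branched_window * sigma and (
                r_mid - r_min
            ) >= 2 * cfg.branched_window * sigma:
                anns.append(GammaAnnotation("BRANCHED", rho_cb=rho_cb,
                                            gamma_densities=tuple(vals),
                                            chi1=best_chi))
                continue
            anns.append(GammaAnnotation("PSEUDO_SER", rho_cb=rho_cb,
                                        gamma_densities=tuple(vals),
                                        chi1=best_chi))
        out.append(anns)
    return out


def annotate_trace_for_phasing(
    trace: Trace,
    annotations: list[list[GammaAnnotation]],
    cell: UnitCell,
    occupancy: float = 0.6,
    b_factor: float = 20.0,
) -> AtomicModel:
    """Polyalanine model plus partially occupied gamma atoms.

    GLY-annotated residues contribute no CB; PSEUDO_SER adds a gamma O at
    1.52 A, PRO/BRANCHED a gamma C, all at ``occupancy``.
    """
    work = trace.copy()
    for chain, anns in zip(work.chains, annotations):
        for res, ann in zip(chain, anns):
            res.name = "GLY" if ann.cls == "GLY" else "ALA"
            for extra in [a for a in list(res.atoms) if a not in BACKBONE_ATOMS + ("CB",)]:
                del res.atoms[extra]
            if ann.cls == "GLY" and "CB" in res.atoms:
                del res.atoms["CB"]
            if ann.cls in ("PSEUDO_SER", "PRO", "BRANCHED") and ann.chi1 is not None:
                bond = {
                    "PSEUDO_SER": PSEUDO_SER_DISTANCE,
                    "PRO": PROLINE_PROBE_DISTANCE,
                    "BRANCHED": GAMMA_PROBE_DISTANCE,
                }[ann.cls]
                name = "OG" if ann.cls == "PSEUDO_SER" else "CG"
                res.ensure_cb()
                res.atoms[name] = place_atom(
                    res.atoms["N"], res.atoms["CA"], res.atoms["CB"],
                    bond, TETRAHEDRAL_ANGLE, ann.chi1,
                )
                res.annotation = ann
    model = work.to_model(cell, polyalanine=False, b_factor=b_factor)
    is_gamma = (model.name == "OG") | (model.name == "CG")
    model.occ[is_gamma] = occupancy
    return model


def secondary_structure_labels(trace: Trace) -> list[list[str]]:
    """Per-residue H/E/C labels from the CA pseudo-torsion pattern.

    Four consecutive CA atoms define a pseudo-torsion: ~50 deg in helices,
    ~-170 deg (wrapping) in strands.
    """
    out = []
    for chain in trace.chains:
        cas = np.array([r.ca for r in chain])
        labels = ["C"] * len(chain)
        for i in range(len(chain) - 3):
            tor = dihedral(cas[i], cas[i + 1], cas[i + 2], cas[i + 3])
            lab = None
            if abs(tor - 50.0) <= 20.0:
                lab = "H"
            elif abs(abs(tor) - 170.0) <= 40.0:
                lab = "E"
            if lab:
                for j in range(i, i + 4):
                    labels[j] = lab
        out.append(labels)
    return out


def residue_type_scores(
    annotation: GammaAnnotation,
    ss_label: str = "C",
    density_table: dict | None = None,
    prior_table: dict | None = None,
) -> dict[str, float]:
    """log P(type) = log P_density(annotation | type) + log P_prior(type | ss),
    normalised so the 20 probabilities sum to one."""
    density_table = density_table or P_DENSITY
    prior_table = prior_table or SS_PRIORS
    dens = density_table[annotation.cls]
    prior = prior_table.get(ss_label, prior_table["C"])
    logp = {aa: np.log(dens[aa]) + np.log(prior[aa]) for aa in AMINO_ACIDS}
    mx = max(logp.values())
    total = np.log(sum(np.exp(v - mx) for v in logp.values())) + mx
    return {aa: v - total for aa, v in logp.items()}


def _score_matrix(annotations, ss_labels) -> np.ndarray:
    """(n_residues, 20) log-score matrix for one chain."""
    rows = []
    for ann, lab in zip(annotations, ss_labels):
        scores = residue_type_scores(ann, lab)
        rows.append([scores[aa] for aa in AMINO_ACIDS])
    return np.array(rows)


def _expected_sulfur_site(res: Residue, aa: str) -> list[np.ndarray]:
    """Candidate S/Se positions if this residue were Cys (SG) or Met (SD)."""
    res.ensure_cb()
    sites = []
    for chi in STAGGERED_CHI1:
        g = place_atom(res.atoms["N"], res.atoms["CA"], res.atoms["CB"],
                       1.81, TETRAHEDRAL_ANGLE, chi)
        if aa == "C":
            sites.append(g)
        else:  # Met SD: one bond further out along the CB->CG direction
            cg = place_atom(res.atoms["N"], res.atoms["CA"], res.atoms["CB"],
                            1.52, TETRAHEDRAL_ANGLE, chi)
            d = cg - res.atoms["CB"]
            sites.append(cg + d / np.linalg.norm(d) * 1.60)
    return sites


def dock_sequence(
    trace: Trace,
    annotations: list[list[GammaAnnotation]],
    sequence: str,
    markers: MarkerSet | None = None,
    dmap: DensityMap | None = None,
    cfg: SidechainConfig | None = None,
) -> DockResult:
    """Assign the sequence register to each chain, longest chain first.

    Every sliding offset of the sequence (with two dummy residues of
    overhang at each end) is scored as the sum of per-residue log scores;
    dummy positions contribute the mean per-residue score of the real part
    of the window, so offsets with different overhang are comparable.
    Marker-compatible Cys/Met (S) or Met (Se) assignments earn a bonus; a
    marker no assignment explains costs a penalty.  An offset is accepted
    only when it beats the runner-up by ``cfg.dock_margin`` log units;
    sequence ranges claimed by earlier (longer) chains are blocked.
    """
    cfg = cfg or SidechainConfig()
    sequence = sequence.upper()
    n_chains = len(trace.chains)
    ss = secondary_structure_labels(trace)
    order = sorted(range(n_chains), key=lambda i: -len(trace.chains[i]))
    offsets = [UNASSIGNED] * n_chains
    logps = [float("-inf")] * n_chains
    margins = [0.0] * n_chains
    types = [["?"] * len(c) for c in trace.chains]
    diagnostics = []
    blocked = np.zeros(len(sequence), dtype=bool)
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    n_assigned = 0

    for ci in order:
        if cfg.max_docked_chains is not None and n_assigned >= cfg.max_docked_chains:
            diagnostics.append(
                f"chain {ci}: sequence copies exhausted "
                f"({cfg.max_docked_chains} available); unassigned"
            )
            continue
        chain = trace.chains[ci]
        anns = annotations[ci]
        L = len(chain)
        S = len(sequence)
        if L > S + 4:
            diagnostics.append(f"chain {ci}: longer than sequence plus overhang; unassigned")
            continue
        scores = _score_matrix(anns, ss[ci])  # (L, 20)
        cand = []
        for off in range(-2, S - L + 3):
            # chain residue i aligns to sequence index off + i
            real = [(i, off + i) for i in range(L) if 0 <= off + i < S]
            if not real or any(blocked[j] for _, j in real):
                continue
            real_scores = [scores[i, aa_index[sequence[j]]] for i, j in real]
            mean_real = float(np.mean(real_scores))
            total = float(np.sum(real_scores)) + (L - len(real)) * mean_real
            if markers is not None and len(markers):
                total += _marker_term(chain, sequence, off, markers, cfg)
            cand.append((total, off))
        if not cand:
            diagnostics.append(f"chain {ci}: no admissible offsets")
            continue
        cand.sort(key=lambda t: (-t[0], t[1]))
        best, best_off = cand[0]
        margin = best - cand[1][0] if len(cand) > 1 else float("inf")
        margins[ci] = max(margin, 0.0) if np.isfinite(margin) else margin
        if margin < cfg.dock_margin:
            diagnostics.append(
                f"chain {ci}: margin {margin:.2f} below {cfg.dock_margin}; unassigned"
            )
            continue
        offsets[ci] = best_off
        logps[ci] = best
        n_assigned += 1
        for i in range(L):
            j = best_off + i
            if 0 <= j < S:
                blocked[j] = True
                types[ci][i] = sequence[j]
    return DockResult(offsets, logps, margins, types, diagnostics)


def _marker_term(chain, sequence, off, markers: MarkerSet, cfg: SidechainConfig) -> float:
    satisfied = np.zeros(len(markers), dtype=bool)
    total = 0.0
    for i, res in enumerate(chain):
        j = off + i
        if not 0 <= j < len(sequence):
            continue
        aa = sequence[j]
        for mi in range(len(markers)):
            kind = markers.kinds[mi]
            compatible = (kind == "SE" and aa == "M") or (
                kind == "S" and aa in ("C", "M")
            )
            if not compatible or satisfied[mi]:
                continue
            sites = _expected_sulfur_site(res, aa)
            dmin = min(np.linalg.norm(s - markers.positions[mi]) for s in sites)
            if dmin <= cfg.marker_radius:
                total += cfg.marker_bonus
                satisfied[mi] = True
    total -= cfg.marker_penalty * float(np.sum(~satisfied))
    return total


def error_correct(trace: Trace, dmap: DensityMap) -> Trace:
    """Cut connections with outlier Ramachandran angles and weak density.

    The connection between residues i and i+1 is judged by the torsion pair
    (psi_i, phi_{i+1}) against a generous allowed mask, and cut only when
    its mean backbone density is also strictly below both flanking
    connections'.  Chains split at cuts; single residues are dropped.
    """
    out_chains = []
    for chain in trace.chains:
        if len(chain) < 3:
            out_chains.append([r.copy() for r in chain])
            continue
        t = Trace([[r.copy() for r in chain]], validate_geometry=False)
        phi, psi = t.phi_psi(0)
        n_conn = len(chain) - 1
        dens = np.zeros(n_conn)
        for i in range(n_conn):
            atoms = [chain[i].atoms["CA"], chain[i].atoms["C"],
                     chain[i + 1].atoms["N"], chain[i + 1].atoms["CA"]]
            dens[i] = float(np.mean(interpolate_density(dmap, np.array(atoms))))
        cuts = []
        for i in range(n_conn):
            p, q = psi[i], phi[i + 1]
            if np.isnan(p) or np.isnan(q):
                continue
            if ramachandran_allowed(q, p):
                continue
            left = dens[i - 1] if i - 1 >= 0 else np.inf
            right = dens[i + 1] if i + 1 < n_conn else np.inf
            flanks = [f for f in (left, right) if np.isfinite(f)]
            if flanks and all(dens[i] < f for f in flanks):
                cuts.append(i)
        segments = []
        start = 0
        for c in cuts:
            segments.append(chain[start : c + 1])
            start = c + 1
        segments.append(chain[start:])
        for seg in segments:
            if len(seg) >= 2:
                out_chains.append([r.copy() for r in seg])
    return Trace(out_chains, validate_geometry=False)


def _strip_sidechains(res: Residue) -> Residue:
    keep = {a: p for a, p in res.atoms.items() if a in BACKBONE_ATOMS + ("CB",)}
    return Residue(keep, name="ALA", annotation=res.annotation)


def stretch_cc_gate(
    trace: Trace,
    refl: ReflectionSet,
    cell: UnitCell | None = None,
    sg: SpaceGroup | None = None,
) -> Trace:
    """Per stretch (chain), keep side chains only if they do not lower the
    amplitude correlation of the whole model with the data."""
    cell = cell or refl.cell
    sg = sg or refl.spacegroup
    work = trace.copy()
    has_sc = [
        any(set(r.atoms) - set(BACKBONE_ATOMS + ("CB",)) for r in chain)
        for chain in work.chains
    ]
    if not any(has_sc):
        return work
    for ci, chain in enumerate(work.chains):
        if not has_sc[ci]:
            continue
        with_model = work.to_model(cell, polyalanine=False)
        stripped = work.copy()
        stripped.chains[ci] = [_strip_sidechains(r) for r in chain]
        without_model = stripped.to_model(cell, polyalanine=False)
        cc_with = cc_fo_fc(with_model, refl, cell, sg)
        cc_without = cc_fo_fc(without_model, refl, cell, sg)
        if cc_with < cc_without:
            work.chains[ci] = stripped.chains[ci]
    return work


def apply_dock(
    trace: Trace,
    dock: DockResult,
    sequence: str,
    dmap: DensityMap,
) -> Trace:
    """Grow full side chains on docked chains, best-density rotamer each."""
    work = trace.copy()
    sequence = sequence.upper()
    for ci, chain in enumerate(work.chains):
        off = dock.offsets[ci]
        if off is UNASSIGNED:
            continue
        for i, res in enumerate(chain):
            j = off + i
            if not 0 <= j < len(sequence):
                res.name = "ALA"
                continue
            res.name = AA1_TO_3[sequence[j]]
            for extra in [a for a in list(res.atoms) if a not in BACKBONE_ATOMS + ("CB",)]:
                del res.atoms[extra]
            if res.name in ("ALA", "GLY"):
                if res.name == "GLY" and "CB" in res.atoms:
                    del res.atoms["CB"]
                continue
            best_rot, best_rho = None, -np.inf
            for chis in ROTAMERS[res.name]:
                tmp = res.copy()
                grow_sidechain(tmp, chis)
                sc = [p for a, p in tmp.atoms.items()
                      if a not in BACKBONE_ATOMS + ("CB",)]
                rho = float(np.mean(interpolate_density(dmap, np.array(sc)))) if sc else -np.inf
                if rho > best_rho:
                    best_rho, best_rot = rho, chis
            grow_sidechain(res, best_rot)
    return work


def build_sidechains(
    trace: Trace,
    dock: DockResult,
    dmap: DensityMap,
    sequence: str,
    cell: UnitCell,
    b_factor: float = 20.0,
) -> AtomicModel:
    """Full-side-chain model for docked chains (alanine where unassigned)."""
    return apply_dock(trace, dock, sequence, dmap).to_model(
        cell, polyalanine=False, b_factor=b_factor
    )


def exclusion_mask(
    model: AtomicModel,
    grid: tuple[int, int, int],
    cell: UnitCell,
    sg: SpaceGroup,
    radius: float = 2.0,
) -> np.ndarray:
    """Per-voxel flag: within ``radius`` of any symmetry image of the model.

    Flagged voxels are ineligible for gamma probing and side-chain building
    (model-bias exclusion for verification runs).
    """
    if radius <= 0:
        raise ValueError("exclusion radius must be positive")
    n = np.array(grid)
    mask = np.zeros(grid, dtype=bool)
    if len(model) == 0:
        return mask
    frac_all = np.concatenate(
        [model.xyz_frac @ r.T + t for r, t in sg.operators]
    ) % 1.0
    orth = cell.orthogonalization_matrix()
    # bounding box of voxels per atom
    spacing = cell.lengths / n
    reach = np.ceil(radius / spacing).astype(int) + 1
    offs = np.stack(np.meshgrid(*[np.arange(-r, r + 1) for r in reach],
                                indexing="ij"), axis=-1).reshape(-1, 3)
    for f in frac_all:
        centre = np.round(f * n).astype(int)
        vox = (centre + offs) % n
        vox_frac = (centre + offs) / n
        d = (vox_frac - f) @ orth.T
        close = np.linalg.norm(d, axis=1) <= radius
        sel = vox[close]
        mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return mask


def run_extension(
    refl: ReflectionSet,
    start_phases: ReflectionSet,
    trace: Trace,
    sequence: str | None = None,
    markers: MarkerSet | None = None,
    dm_config: DMConfig | None = None,
    cfg: SidechainConfig | None = None,
    reference: ReflectionSet | None = None,
    exclusion_model: AtomicModel | None = None,
):
    """Alternate density-modification blocks with map-interpretation cycles.

    Each interpretation cycle error-corrects the trace, gamma-probes it,
    and feeds the annotated (partial-occupancy gamma) model phases back into
    the next block; once the polyalanine CC reaches ``cfg.dock_cc_gate``
    percent and a sequence is available, sequence docking, side-chain
    building and the per-stretch CC gate run as well.  The solved verdict
    consults the polyalanine CC only.

    Returns ``(final model, final phase set, diagnostics DataFrame)``.
    """
    cfg = cfg or SidechainConfig()
    dm_config = dm_config or DMConfig()
    cell, sg = refl.cell, refl.spacegroup
    if cfg.sequence_docking and sequence is None:
        warnings.warn(
            "sequence docking requested but no sequence provided; "
            "performing gamma tracing only",
            stacklevel=2,
        )
    d_min = float(np.min(refl.d[refl.measured]))
    work_trace = trace.copy()
    current_start = start_phases
    rows = []
    model = work_trace.to_model(cell, polyalanine=True)
    dock = None
    mask = None
    last_fingerprint = None
    if exclusion_model is not None and len(exclusion_model):
        from .maps import grid_for_resolution

        grid = grid_for_resolution(cell, d_min, dm_config.oversampling)
        mask = exclusion_mask(exclusion_model, grid, cell, sg, cfg.exclusion_radius)

    for cycle in range(cfg.n_interpretation_cycles):
        phases, dm_map, dm_diag = run_dm(refl, current_start, dm_config, reference)
        dmap = map_from_phases(phases, cell, sg, d_min=d_min,
                               oversampling=dm_config.oversampling)
        work_trace = error_correct(work_trace, dmap)
        annotations = gamma_probe(work_trace, dmap, cfg, mask=mask)
        model = annotate_trace_for_phasing(
            work_trace, annotations, cell, occupancy=cfg.gamma_occupancy
        )
        polyala = work_trace.to_model(cell, polyalanine=True)
        cc_polyala = cc_fo_fc(polyala, refl, cell, sg)
        cc_full = cc_polyala
        if (
            cfg.sequence_docking
            and sequence is not None
            and cc_polyala >= cfg.dock_cc_gate
        ):
            dock = dock_sequence(work_trace, annotations, sequence, markers, dmap, cfg)
            docked = apply_dock(work_trace, dock, sequence, dmap)
            gated = stretch_cc_gate(docked, refl, cell, sg)
            model = gated.to_model(cell, polyalanine=False)
            cc_full = cc_fo_fc(model, refl, cell, sg)
        # Trace-derived phases are combined into the current state with
        # sigma_A-style partial-model weights — but essentially-new model
        # information only once: recombining an unchanged model every
        # cycle double-counts its information and drags the phases back
        # toward it.  Only the first cycle and a newly successful sequence
        # docking count as new information; once the model has converged
        # the loop stops (additional cycles would be no-ops).
        assigned = (
            tuple(sorted(o for o in dock.offsets if o is not UNASSIGNED))
            if dock is not None
            else ()
        )
        converged = last_fingerprint is not None and assigned == last_fingerprint
        row = {
            "interpretation_cycle": cycle + 1,
            "n_residues": work_trace.n_residues,
            "cc_polyala": cc_polyala,
            "cc_full": cc_full,
            "mean_fom": float(np.nanmean(phases.fom)),
            "docked": dock is not None and any(o is not UNASSIGNED for o in dock.offsets),
            "solved": cc_polyala > cfg.solved_cc,
            "converged": converged,
        }
        if reference is not None:
            pc = phase_error(phases, reference)
            row["mpe"], row["wmpe"] = pc.mpe, pc.wmpe
        rows.append(row)
        if converged:
            final_phases = phases
            break
        fcalc = compute_structure_factors(model, cell, sg, d_min, hkl=refl.hkl)
        from .densitymod import _sigma_a_weights

        d = cell.d_spacing(refl.hkl)
        w_model = _sigma_a_weights(refl.F, fcalc.F, d, np.ones(len(d), dtype=bool))
        current_start = combine_phases(_as_prior(refl, phases), fcalc, w_calc=w_model)
        last_fingerprint = assigned
    else:
        final_phases, dm_map, dm_diag = run_dm(refl, current_start, dm_config, reference)
    if reference is not None and rows:
        pc = phase_error(final_phases, reference)
        rows[-1]["final_mpe"], rows[-1]["final_wmpe"] = pc.mpe, pc.wmpe
    return model, final_phases, pd.DataFrame(rows)


def _as_prior(refl: ReflectionSet, start_phases: ReflectionSet) -> ReflectionSet:
    prior = refl.copy()
    prior.phi[:] = np.nan
    prior.fom[:] = np.nan
    ia, ib = prior.match(start_phases)
    prior.phi[ia] = start_phases.phi[ib]
    prior.fom[ia] = start_phases.fom[ib]
    return prior
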