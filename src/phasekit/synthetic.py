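"""Synthetic toy crystals with known ground truth.

Generates ideal-geometry protein folds (helix, strand, helix pair), places
them in a unit cell sized to a target solvent fraction, simulates
diffraction amplitudes with controllable noise, perturbs the true phases
to a requested weighted mean phase error, and derives partial polyalanine
traces — everything needed to exercise density modification and map
interpretation offline, standing in for deposited experimental data sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import build_backbone, grow_sidechain
from .model import AtomicModel
from .metrics import wrap_angle
from .reflections import ReflectionSet
from .resdata import AA1_TO_3, ROTAMERS, SIDECHAIN_TOPOLOGY
from .sfcalc import compute_structure_factors
from .symmetry import SpaceGroup, UnitCell
from .trace import CA_CA_MAX, CA_CA_MIN, Residue, Trace

__all__ = [
    "SyntheticSpec",
    "build_structure",
    "build_trace_residues",
    "simulate_data",
    "perturb_phases",
    "make_trace",
    "small_helix_fixture",
    "medium_fixture",
]

FOLD_ANGLES = {"helix": (-57.0, -47.0), "strand": (-120.0, 120.0)}


@dataclass
class SyntheticSpec:
    """Recipe for one toy crystal."""

    sequence: str = "AVLSTGKDEF"
    fold: str = "helix"            # helix | strand | helix-pair
    spacegroup: str = "P1"
    d_min: float = 1.5
    solvent_fraction: float = 0.5
    noise: float = 0.02            # fractional amplitude noise
    target_wmpe: float = 65.0      # degrees, for the perturbed start
    b_factor: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if len(self.sequence) < 4:
            raise ValueError("sequence must have at least 4 residues")
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if not 0.0 <= self.target_wmpe <= 90.0:
            raise ValueError("target wMPE must lie in [0, 90] degrees")
        if self.fold not in ("helix", "strand", "helix-pair"):
            raise ValueError(f"unknown fold {self.fold!r}")




def _align_axis_to_x(chain: list[Residue]) -> None:
    """Rotate a chain so its CA end-to-end axis lies along +x."""
    cas = np.array([r.ca for r in chain])
    centre = cas.mean(axis=0)
    a = cas[-1] - cas[0]
    a /= np.linalg.norm(a)
    b = np.array([1.0, 0.0, 0.0])
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-9:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    for res in chain:
        for atom in res.atoms:
            res.atoms[atom] = rot @ (res.atoms[atom] - centre)


def build_trace_residues(sequence: str, fold: str) -> list[list[Residue]]:
    """Ideal-geometry chains (orthogonal coordinates, centred later)."""
    if fold == "helix-pair":
        half = len(sequence) // 2
        parts = [sequence[:half], sequence[half:]]
        folds = ["helix", "helix"]
    else:
        parts, folds = [sequence], [fold]
    chains = []
    offset = np.zeros(3)
    for part, f, k in zip(parts, folds, range(len(parts))):
        phi, psi = FOLD_ANGLES[f]
        bb = build_backbone(len(part), phi, psi)
        chain = []
        for aa1, atoms in zip(part, bb):
            res = Residue(dict(atoms), name=AA1_TO_3[aa1.upper()])
            chain.append(res)
        _align_axis_to_x(chain)
        # antiparallel second helix, displaced sideways
        if k == 1:
            cas = np.array([r.ca for r in chain])
            centre = cas.mean(axis=0)
            axis_flip = np.diag([-1.0, 1.0, 1.0])
            for res in chain:
                for a in res.atoms:
                    res.atoms[a] = (res.atoms[a] - centre) @ axis_flip + centre
            offset = np.array([0.0, 11.5, 1.5])
            for res in chain:
                for a in res.atoms:
                    res.atoms[a] = res.atoms[a] + offset
        for res in chain:
            if SIDECHAIN_TOPOLOGY[res.name]:
                grow_sidechain(res, ROTAMERS[res.name][0])
        chains.append(chain)
    return chains


def _cell_for_solvent_fraction(
    positions: np.ndarray,
    target_fs: float,
    n_copies: int = 1,
    pad_weights=(1.0, 1.0, 1.0),
    atom_radius: float = 2.2,
):
    """Orthorhombic-ish cell padded so the atom-mask volume fraction of all
    symmetry copies hits 1 - target_fs (per-axis weighted padding, solved
    by bisection).  Only the single-copy mask is evaluated; copies scale it."""
    span = positions.max(axis=0) - positions.min(axis=0)
    w = np.asarray(pad_weights, dtype=float)

    def fs_for(pad):
        dims = np.maximum(span + pad * w, 8.0)
        cell = UnitCell(*dims)
        return 1.0 - n_copies * _mask_fraction(positions, cell, atom_radius)

    lo, hi = 2.0, 120.0
    for _ in range(16):
        mid = 0.5 * (lo + hi)
        if fs_for(mid) < target_fs:
            lo = mid
        else:
            hi = mid
    pad = 0.5 * (lo + hi)
    dims = np.maximum(span + pad * w, 8.0)
    return UnitCell(*dims), pad


def _mask_fraction(positions, cell: UnitCell, radius: float, grid_step: float = 0.7):
    """Fraction of cell voxels within ``radius`` of any (wrapped) atom."""
    n = np.maximum((cell.lengths / grid_step).astype(int), 8)
    frac = cell.fractionalize(positions) % 1.0
    axes = [np.arange(k) / k for k in n]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid_frac = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    mask = np.zeros(len(grid_frac), dtype=bool)
    orth = cell.orthogonalization_matrix()
    for f in frac:
        d = grid_frac - f
        d -= np.round(d)
        dist = np.linalg.norm(d @ orth.T, axis=1)
        mask |= dist <= radius
    return float(mask.mean())


_STRUCTURE_CACHE: dict = {}
_TRUE_SF_CACHE: dict = {}


def build_structure(spec: SyntheticSpec):
    """Ground-truth model in a cell hitting the target solvent fraction.

    Returns ``(model, cell, spacegroup, trace_residues)``; the trace
    residues carry the full side-chain atoms in the same frame.  The
    construction is deterministic given (sequence, fold, space group,
    solvent fraction), so results are cached.
    """
    key = (spec.sequence, spec.fold, spec.spacegroup,
           round(spec.solvent_fraction, 4), round(spec.b_factor, 3))
    cached = _STRUCTURE_CACHE.get(key)
    if cached is not None:
        model, cell, sg, trace = cached
        return model.copy(), cell, sg, trace.copy()
    out = _build_structure_impl(spec)
    _STRUCTURE_CACHE[key] = (out[0].copy(), out[1], out[2], out[3].copy())
    return out


def _build_structure_impl(spec: SyntheticSpec):
    chains = build_trace_residues(spec.sequence, spec.fold)
    sg_probe = SpaceGroup(spec.spacegroup)
    if len(sg_probe) > 1:
        # long molecular axis along the screw direction (b for P21) keeps
        # symmetry mates apart at reasonable solvent fractions
        rot = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        for chain in chains:
            for res in chain:
                for a in res.atoms:
                    res.atoms[a] = rot @ res.atoms[a]
    all_pos = np.array(
        [p for chain in chains for r in chain for p in r.atoms.values()]
    )
    centre = all_pos.mean(axis=0)
    sg = SpaceGroup(spec.spacegroup)
    # pad mostly perpendicular to the screw axis: mates stack end-to-end
    # along it and need lateral clearance
    weights = (1.4, 0.3, 1.4) if len(sg) > 1 else (1.0, 1.0, 1.0)
    cell, _ = _cell_for_solvent_fraction(
        all_pos - centre, spec.solvent_fraction, n_copies=len(sg), pad_weights=weights
    )
    shift_frac = _best_placement(all_pos - centre, cell, sg)
    shift = cell.orthogonalize(shift_frac)
    for chain in chains:
        for res in chain:
            for a in res.atoms:
                res.atoms[a] = res.atoms[a] - centre + shift
    if len(sg) > 1:
        _check_packing(chains, cell, sg)
    trace = Trace([[r.copy() for r in chain] for chain in chains])
    model = trace.to_model(cell, polyalanine=False, b_factor=spec.b_factor)
    # restore true residue names lost to the polyalanine flag
    return model, cell, sg, trace


def _min_mate_distance(frac: np.ndarray, cell: UnitCell, sg: SpaceGroup) -> float:
    orth = cell.orthogonalization_matrix()
    best = np.inf
    for r, t in sg.operators[1:]:
        mate = frac @ r.T + t
        d = frac[:, None, :] - mate[None, :, :]
        d -= np.round(d)
        dist = np.linalg.norm(d @ orth.T, axis=2)
        best = min(best, float(dist.min()))
    return best


def _best_placement(centred_pos: np.ndarray, cell: UnitCell, sg: SpaceGroup) -> np.ndarray:
    """Molecular origin (fractional) maximising symmetry-mate clearance."""
    if len(sg) == 1:
        return np.full(3, 0.5)
    # sample a subset of atoms for speed; clearance is verified afterwards
    sub = centred_pos[:: max(1, len(centred_pos) // 150)]
    grid = np.linspace(0.05, 0.95, 10)
    best, best_shift = -np.inf, np.full(3, 0.25)
    for sx in grid:
        for sz in grid:
            shift = np.array([sx, 0.25, sz])
            frac = cell.fractionalize(sub) + shift
            d = _min_mate_distance(frac, cell, sg)
            if d > best:
                best, best_shift = d, shift
    return best_shift


def _check_packing(chains, cell: UnitCell, sg: SpaceGroup, min_dist: float = 2.0):
    pos = np.array([r.atoms[a] for c in chains for r in c for a in r.atoms])
    frac = cell.fractionalize(pos)
    for r, t in sg.operators[1:]:
        mate = frac @ r.T + t
        d = frac[:, None, :] - mate[None, :, :]
        d -= np.round(d)
        dist = np.linalg.norm(d @ cell.orthogonalization_matrix().T, axis=2)
        if dist.min() < min_dist:
            raise ValueError(
                f"impossible packing: symmetry mates clash at {dist.min():.2f} A"
            )


def simulate_data(model: AtomicModel, spec: SyntheticSpec, cell: UnitCell, sg: SpaceGroup):
    """(true ReflectionSet with phases, noisy observed ReflectionSet)."""
    key = (spec.sequence, spec.fold, spec.spacegroup,
           round(spec.solvent_fraction, 4), round(spec.b_factor, 3),
           round(spec.d_min, 4), len(model))
    true = _TRUE_SF_CACHE.get(key)
    if true is None:
        true = compute_structure_factors(model, cell, sg, spec.d_min)
        _TRUE_SF_CACHE[key] = true
    true = true.copy()
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, spec.noise, len(true)) if spec.noise > 0 else np.zeros(len(true))
    fobs = true.F * (1.0 + eps)
    fobs = np.clip(fobs, 0.0, None)
    obs = ReflectionSet(
        true.hkl.copy(),
        F=fobs,
        sigF=np.maximum(spec.noise * true.F, 1e-6),
        cell=cell,
        spacegroup=sg,
    )
    return true, obs


def perturb_phases(
    true: ReflectionSet,
    target_wmpe: float,
    seed: int = 0,
    heterogeneity: float = 0.6,
) -> ReflectionSet:
    """Start phases at a requested wMPE via wrapped-normal phase noise.

    Real starting phase sets (fragment or substructure derived) are not
    uniformly bad: errors grow with resolution and scatter strongly between
    reflections.  The per-reflection noise width is therefore
    sigma_i = sigma0 * (1/d_i) / <1/d> * lognormal(0, heterogeneity),
    with the overall scale sigma0 solved by bisection so the realised
    (weight-uniform) error is within a fraction of a degree of the target.
    Figures of merit are set per reflection to exp(-sigma_i^2/2), the
    expected cosine of the wrapped-normal distribution, so the fom
    distribution is informative the way an experimental one is.
    """
    out = true.copy()
    if target_wmpe <= 0:
        out.fom = np.ones(len(out))
        return out
    rng = np.random.default_rng(seed)
    n = len(true)
    d = true.cell.d_spacing(true.hkl) if true.cell is not None else np.ones(n)
    rel = (1.0 / d) / np.mean(1.0 / d)
    scale = rel * np.exp(rng.normal(0.0, heterogeneity, n))
    eps = rng.normal(0.0, 1.0, n)

    def realised(sigma0):
        return float(np.mean(wrap_angle(sigma0 * scale * eps)))

    lo, hi = 0.0, 3000.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if realised(mid) < target_wmpe:
            lo = mid
        else:
            hi = mid
    sigma0 = 0.5 * (lo + hi)
    out.phi = (true.phi + sigma0 * scale * eps) % 360.0
    sigma_rad = np.radians(sigma0 * scale)
    out.fom = np.clip(np.exp(-0.5 * sigma_rad**2), 0.0, 1.0)
    return out


def make_trace(
    truth: Trace,
    completeness: float = 0.5,
    displacement_rms: float = 0.3,
    seed: int = 0,
) -> Trace:
    """Contiguous partial polyalanine trace with Gaussian coordinate jitter."""
    if not 0.0 < completeness <= 1.0:
        raise ValueError("completeness must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    chains = []
    for chain in truth.chains:
        keep = max(2, int(round(completeness * len(chain))))
        start = int(rng.integers(0, len(chain) - keep + 1)) if keep < len(chain) else 0
        part = []
        for res in chain[start : start + keep]:
            atoms = {
                a: res.atoms[a] for a in ("N", "CA", "C", "O", "CB") if a in res.atoms
            }
            part.append(Residue(atoms, name="ALA"))
        chains.append(part)
    if displacement_rms > 0:
        sigma = displacement_rms / np.sqrt(3.0)
        for chain in chains:
            base = {id(res): {a: p.copy() for a, p in res.atoms.items()} for res in chain}
            for _attempt in range(50):  # redraw until the CA-CA envelope holds
                for res in chain:
                    for a in res.atoms:
                        res.atoms[a] = base[id(res)][a] + rng.normal(0.0, sigma, 3)
                cas = np.array([r.ca for r in chain])
                d = np.linalg.norm(np.diff(cas, axis=0), axis=1)
                if len(d) == 0 or (d.min() >= CA_CA_MIN and d.max() <= CA_CA_MAX):
                    break
    return Trace(chains)


# -- packaged fixtures ------------------------------------------------------

def small_helix_fixture(seed: int = 0):
    """10-residue helix, P1, 1.5 A."""
    spec = SyntheticSpec(
        sequence="AVLSTGKDEF", fold="helix", spacegroup="P1", d_min=1.5, seed=seed
    )
    model, cell, sg, trace = build_structure(spec)
    true, obs = simulate_data(model, spec, cell, sg)
    return {"spec": spec, "model": model, "cell": cell, "sg": sg,
            "trace": trace, "true": true, "obs": obs}


def medium_fixture(seed: int = 0, target_wmpe: float = 65.0):
    """30-residue helix pair, P2(1), 2.0 A, 2% amplitude noise."""
    spec = SyntheticSpec(
        sequence="ADKVFLESTMYGNQIRLHWAVDEKFSTLYN",
        fold="helix-pair",
        spacegroup="P21",
        d_min=2.0,
        noise=0.02,
        target_wmpe=target_wmpe,
        seed=seed,
    )
    model, cell, sg, trace = build_structure(spec)
    true, obs = simulate_data(model, spec, cell, sg)
    start = perturb_phases(true, spec.target_wmpe, seed=seed)
    return {"spec": spec, "model": model, "cell": cell, "sg": sg,
            "trace": trace, "true": true, "obs": obs, "start": start}
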