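"""Sphere-of-influence density modification.

The map is classified voxel-by-voxel from the variance of the density on a
spherical surface of radius 2.42 A (a typical 1,3 interatomic distance)
centred at each voxel: high variance is protein-like, low variance
solvent-like, with no explicit solvent boundary.  Solvent density is
flipped, rho' = -gamma * rho (gamma defaults to 1.1); protein density is
truncated at zero and optionally sharpened with

    rho_mod = [rho^4 / (nu^2 sigma^2(rho) + rho^2)]^(1/2),

where sigma(rho) is the global map standard deviation and nu grows with
resolution.  Intermediate voxels get a weighted mean of both corrections.
Each cycle the modified map is inverted, and the calculated phases are
recombined with the starting phase distribution under a resolution-binned
Fo/Fc agreement weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import fftn, ifftn, fftfreq

from .maps import DensityMap, grid_for_resolution, invert_map, map_from_phases
from .reflections import ReflectionSet, unique_hkl

__all__ = [
    "DMConfig",
    "VarianceMap",
    "fibonacci_sphere",
    "sphere_variance",
    "classify_voxels",
    "flip",
    "sharpen",
    "default_nu",
    "modify_map",
    "combine_phases",
    "free_lunch_extend",
    "run_dm",
]


@dataclass
class DMConfig:
    """Tunable parameters of the density-modification cycle."""

    solvent_fraction: float = 0.5
    gamma: float = 1.1              # solvent flip factor
    sphere_radius: float = 2.42     # A, variance-sphere radius
    n_sphere_points: int = 92
    nu: float | None = None         # sharpening strength; None = resolution default
    n_cycles: int = 20
    sharpen_weight: float = 1.0     # 1.0 experimental phases, 0.5 fragment-derived
    flip_only: bool = False
    free_lunch_dmin: float | None = None
    quantile_band: float = 0.10     # width of the solvent/protein crossover, voxel fraction
    oversampling: float = 4.0
    relaxation: float = 0.7         # step size: rho <- (1-r) rho + r modify(rho)
    variance_smoothing: float = 0.75  # A, Gaussian smoothing of the variance field
    free_fraction: float = 0.07     # cross-validation reflections for weighting
    n_weight_bins: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0.0 < self.solvent_fraction < 1.0:
            raise ValueError("solvent fraction must lie in (0, 1)")
        if self.sphere_radius <= 0:
            raise ValueError("sphere radius must be positive")


@dataclass
class VarianceMap:
    values: np.ndarray  # V >= 0 per voxel

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("variance map must be non-negative")
        self.values = np.clip(self.values, 0.0, None)


def default_nu(d_min: float) -> float:
    """Sharpening strength, larger at higher resolution: 2.5/d_min in [0.5, 5]."""
    return float(np.clip(2.5 / d_min, 0.5, 5.0))


_SPHERE_KERNELS: dict = {}  # (shape, cell, radius, n points) -> FFT kernel


def _sphere_kernel(shape, frac_offsets, cell, cfg):
    key = (
        shape,
        tuple(np.round(cell.lengths, 6)),
        (cell.alpha, cell.beta, cell.gamma),
        cfg.sphere_radius,
        cfg.n_sphere_points,
    )
    kern = _SPHERE_KERNELS.get(key)
    if kern is None:
        freqs = [fftfreq(k, 1.0 / k) for k in shape]
        kx, ky, kz = np.meshgrid(*freqs, indexing="ij")
        kern = np.zeros(shape, dtype=complex)
        for d in frac_offsets:
            kern += np.exp(2j * np.pi * (kx * d[0] + ky * d[1] + kz * d[2]))
        kern /= len(frac_offsets)
        _SPHERE_KERNELS[key] = kern
        if len(_SPHERE_KERNELS) > 16:
            _SPHERE_KERNELS.pop(next(iter(_SPHERE_KERNELS)))
    return kern


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def sphere_variance(dmap: DensityMap, cfg: DMConfig, method: str = "fft") -> VarianceMap:
    """Variance of the density over the 2.42 A spherical surface at each voxel.

    ``method='fft'`` evaluates the Fibonacci point set through Fourier
    phase shifts (spectral interpolation of the band-limited map, one pair
    of FFTs regardless of point count); ``method='points'`` samples the
    same points with trilinear interpolation via grid rolls.
    """
    if np.any(dmap.spacing() >= cfg.sphere_radius):
        raise ValueError("map grid spacing must be finer than the sphere radius")
    pts = fibonacci_sphere(cfg.n_sphere_points) * cfg.sphere_radius
    frac = dmap.cell.fractionalize(pts)  # fractional offsets
    rho = dmap.values
    n = np.array(dmap.shape)
    if method == "fft":
        # The mean over the point set is exact through Fourier phase shifts.
        # rho^2 is not band-limited on the working grid, so it is formed on
        # a spectrally zero-padded 2x grid (where it is) before averaging.
        fine = tuple(2 * k for k in dmap.shape)
        kern = _sphere_kernel(dmap.shape, frac, dmap.cell, cfg)
        kern2 = _sphere_kernel(fine, frac, dmap.cell, cfg)
        s1 = np.real(ifftn(fftn(rho) * kern))
        spec = fftn(rho)
        spec2 = np.zeros(fine, dtype=complex)
        ix = [np.r_[0 : k // 2, k // 2 - k :0] for k in dmap.shape]
        spec2[np.ix_(*ix)] = spec
        rho_fine = np.real(ifftn(spec2)) * 8.0
        s2_fine = np.real(ifftn(fftn(rho_fine * rho_fine) * kern2))
        s2 = s2_fine[::2, ::2, ::2]
        return VarianceMap(s2 - s1 * s1)
    if method == "points":
        s1 = np.zeros_like(rho)
        s2 = np.zeros_like(rho)
        for d in frac:
            g = d * n
            i0 = np.floor(g).astype(int)
            w = g - i0
            sample = np.zeros_like(rho)
            for corner in range(8):
                off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
                weight = np.prod(np.where(off == 1, w, 1.0 - w))
                sample += weight * np.roll(rho, shift=tuple(-(i0 + off)), axis=(0, 1, 2))
            s1 += sample
            s2 += sample * sample
        s1 /= len(frac)
        s2 /= len(frac)
        return VarianceMap(s2 - s1 * s1)
    raise ValueError(f"unknown method {method!r}")


def classify_voxels(varmap: VarianceMap, fs: float, band: float = 0.10) -> np.ndarray:
    """Protein-likeness weight w_p in [0, 1] from the variance ranking.

    The lowest-variance ``fs - band/2`` fraction of voxels is pure solvent
    (w_p = 0), the top ``1 - fs - band/2`` pure protein (w_p = 1), with a
    linear crossover in rank in between.  Deterministic given the map.
    """
    v = varmap.values.ravel()
    order = np.argsort(v, kind="stable")
    rank = np.empty_like(order, dtype=float)
    rank[order] = np.arange(len(v))
    rank /= max(len(v) - 1, 1)
    lo = fs - band / 2.0
    w = np.clip((rank - lo) / max(band, 1e-12), 0.0, 1.0)
    return w.reshape(varmap.values.shape)


def flip(rho, gamma: float = 1.1):
    """Solvent flipping: rho' = -gamma * rho."""
    return -gamma * np.asarray(rho)


def sharpen(rho, nu: float, sigma_rho: float):
    """rho_mod = [rho^4 / (nu^2 sigma^2(rho) + rho^2)]^(1/2), for rho > 0."""
    rho = np.asarray(rho, dtype=float)
    pos = np.clip(rho, 0.0, None)
    denom = nu * nu * sigma_rho * sigma_rho + pos * pos
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(np.where(denom > 0, pos**4 / np.where(denom > 0, denom, 1.0), 0.0))
    return out


def modify_map(
    dmap: DensityMap,
    varmap: VarianceMap,
    cfg: DMConfig,
    weights: np.ndarray | None = None,
) -> DensityMap:
    """Weighted mean of the protein and solvent corrections per voxel.

    ``weights`` overrides the variance-derived protein-likeness w_p."""
    if weights is None:
        w_p = classify_voxels(varmap, cfg.solvent_fraction, cfg.quantile_band)
    else:
        w_p = np.asarray(weights, dtype=float)
    rho = dmap.values
    truncated = np.clip(rho, 0.0, None)
    sw = 0.0 if cfg.flip_only else cfg.sharpen_weight
    if sw > 0.0:
        nu = cfg.nu if cfg.nu is not None else default_nu(dmap.d_min or 2.0)
        protein = (1.0 - sw) * truncated + sw * sharpen(rho, nu, dmap.sigma)
    else:
        protein = truncated
    out = w_p * protein + (1.0 - w_p) * flip(rho, cfg.gamma)
    return DensityMap(out, dmap.cell, dmap.spacegroup, dmap.d_min)


def _resolution_bin_weights(d, fo, fc, n_bins: int = 10):
    """Per-reflection calculated-phase weight from binned Fo/Fc correlation."""
    order = np.argsort(d)
    n = len(d)
    n_bins = max(1, min(n_bins, n // 20)) if n >= 40 else 1
    edges = np.array_split(order, n_bins)
    w = np.zeros(n)
    for idx in edges:
        a, b = fo[idx], fc[idx]
        if len(idx) >= 3 and np.std(a) > 0 and np.std(b) > 0:
            cc = float(np.corrcoef(a, b)[0, 1])
        else:
            cc = 0.0
        w[idx] = np.clip(cc, 0.0, 0.95)
    return w


def _kappa_from_fom(m: np.ndarray) -> np.ndarray:
    """Inverse of A(kappa) = I1(kappa)/I0(kappa) (Best-Fisher approximation)."""
    m = np.clip(np.asarray(m, dtype=float), 0.0, 0.999)
    k = np.where(
        m < 0.53,
        2 * m + m**3 + 5 * m**5 / 6,
        np.where(
            m < 0.85,
            -0.4 + 1.39 * m + 0.43 / np.maximum(1 - m, 1e-6),
            1.0 / np.maximum(m**3 - 4 * m**2 + 3 * m, 1e-6),
        ),
    )
    return np.clip(k, 0.0, 60.0)


def _fom_from_kappa(k: np.ndarray) -> np.ndarray:
    from scipy.special import i0e, i1e

    k = np.asarray(k, dtype=float)
    return np.where(k > 0, i1e(k) / np.maximum(i0e(k), 1e-12), 0.0)


def _hl_centroid(hl: np.ndarray, n_steps: int = 120):
    """Centroid phase (deg) and fom of HL-coded phase distributions."""
    phi = np.linspace(0.0, 2 * np.pi, n_steps, endpoint=False)
    c1, s1 = np.cos(phi), np.sin(phi)
    c2, s2 = np.cos(2 * phi), np.sin(2 * phi)
    logp = (
        np.outer(hl[:, 0], c1)
        + np.outer(hl[:, 1], s1)
        + np.outer(hl[:, 2], c2)
        + np.outer(hl[:, 3], s2)
    )
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    vec = p @ np.exp(1j * phi)
    return np.degrees(np.angle(vec)) % 360.0, np.abs(vec)


def _sigma_a_weights(
    fo: np.ndarray,
    fc: np.ndarray,
    d: np.ndarray,
    free: np.ndarray,
    n_bins: int = 8,
) -> np.ndarray:
    """Per-reflection calculated-phase weight, sigma_A style.

    The Fo/Fc agreement is estimated per resolution bin on the held-out
    (free) reflections only, so it is not inflated by the amplitudes used
    in the synthesis; the per-reflection weight modulates the binned
    agreement by the normalised amplitude product, m = I1(X)/I0(X) with
    X = 2 sigma_A Eo Ec / (1 - sigma_A^2).
    """
    from scipy.special import i0e, i1e

    n = len(fo)
    order = np.argsort(d)
    n_bins = max(1, min(n_bins, max(1, n // 40)))
    w = np.zeros(n)
    for idx in np.array_split(order, n_bins):
        fidx = idx[free[idx]]
        if len(fidx) >= 5 and np.std(fo[fidx]) > 0 and np.std(fc[fidx]) > 0:
            cc = float(np.corrcoef(fo[fidx], fc[fidx])[0, 1])
        elif np.std(fo[idx]) > 0 and np.std(fc[idx]) > 0:
            cc = float(np.corrcoef(fo[idx], fc[idx])[0, 1])
        else:
            cc = 0.0
        s_a = np.sqrt(np.clip(cc, 0.0, 0.97))
        eo = fo[idx] / max(np.sqrt(np.mean(fo[idx] ** 2)), 1e-12)
        ec = fc[idx] / max(np.sqrt(np.mean(fc[idx] ** 2)), 1e-12)
        x = 2.0 * s_a * eo * ec / max(1.0 - s_a * s_a, 1e-2)
        w[idx] = np.clip(i1e(x) / i0e(x), 0.0, 0.99)
    return w


def combine_phases(
    experimental: ReflectionSet,
    calculated: ReflectionSet,
    n_bins: int = 10,
    hl_scale: float = 2.0,
    w_calc: np.ndarray | None = None,
) -> ReflectionSet:
    """Recombine calculated phases with the starting phase distribution.

    With HL coefficients present the calculated phase enters as an (A, B)
    increment weighted by the resolution-binned Fo/Fc correlation and the
    centroid of the updated distribution is returned; otherwise unit phase
    vectors are combined with weights (m_exp, w_calc).  Experimental
    amplitudes are passed through untouched on measured reflections.
    """
    if experimental.cell is not None and calculated.cell is not None:
        if not np.allclose(
            experimental.cell.lengths, calculated.cell.lengths
        ) or not np.allclose(
            (experimental.cell.alpha, experimental.cell.beta, experimental.cell.gamma),
            (calculated.cell.alpha, calculated.cell.beta, calculated.cell.gamma),
        ):
            raise ValueError("mismatched unit cells")
    ia, ib = experimental.match(calculated)
    if len(ia) != np.sum(experimental.measured):
        missing = np.sum(experimental.measured) - len(ia)
        if missing > 0:
            raise ValueError(f"{missing} measured reflections missing from calculated set")
    out = experimental.copy()
    d = experimental.cell.d_spacing(experimental.hkl[ia])
    if w_calc is None:
        w_calc = _resolution_bin_weights(d, experimental.F[ia], calculated.F[ib], n_bins)
    else:
        w_calc = np.asarray(w_calc, dtype=float)[ia]
    phi_c = np.radians(calculated.phi[ib])
    if experimental.hl is not None:
        hl = experimental.hl[ia].copy()
        hl[:, 0] += hl_scale * w_calc * np.cos(phi_c)
        hl[:, 1] += hl_scale * w_calc * np.sin(phi_c)
        phi_out, fom_out = _hl_centroid(hl)
        out.phi[ia] = phi_out
        out.fom[ia] = fom_out
        out.hl = experimental.hl  # prior distribution is kept, not accumulated
    else:
        m_exp = np.where(np.isnan(experimental.fom[ia]),
                         np.where(np.isnan(experimental.phi[ia]), 0.0, 1.0),
                         experimental.fom[ia])
        phi_e = np.radians(np.nan_to_num(experimental.phi[ia]))
        v = m_exp * np.exp(1j * phi_e) + w_calc * np.exp(1j * phi_c)
        out.phi[ia] = np.degrees(np.angle(v)) % 360.0
        out.fom[ia] = np.clip(np.abs(v), 0.0, 1.0)
        zero = (m_exp + w_calc) <= 1e-12
        if np.any(zero):
            out.phi[ia[zero]] = calculated.phi[ib[zero]]
            out.fom[ia[zero]] = 0.0
    return out


def free_lunch_extend(
    refl: ReflectionSet, dm_map: DensityMap, target_dmin: float
) -> ReflectionSet:
    """Fill unmeasured reflections (interior gaps and beyond the limit)
    with amplitudes and phases from the modified map; measured amplitudes
    are never overwritten."""
    cell, sg = refl.cell, refl.spacegroup
    hkl_ext = unique_hkl(cell, sg, target_dmin)
    lut = refl.index_map()
    known = np.array([tuple(h) in lut for h in hkl_ext])
    calc = invert_map(dm_map, target_dmin, hkl=hkl_ext)
    # scale calculated amplitudes to the measured ones
    ia, ib = refl.match(calc)
    meas = refl.measured[ia]
    denom = float(np.sum(calc.F[ib[meas]] ** 2))
    scale = float(np.sum(refl.F[ia[meas]] * calc.F[ib[meas]])) / denom if denom > 0 else 1.0
    ext_fom = 0.5 * float(np.nanmean(refl.fom)) if np.any(~np.isnan(refl.fom)) else 0.3

    new_rows = ~known
    out = refl.copy()
    # update unmeasured rows already present
    unmeas = ~out.measured
    if np.any(unmeas):
        ja, jb = out.select(unmeas).match(calc)
        idx = np.where(unmeas)[0][ja]
        out.F[idx] = scale * calc.F[jb]
        out.phi[idx] = calc.phi[jb]
        out.fom[idx] = ext_fom
    if np.any(new_rows):
        add = ReflectionSet(
            hkl_ext[new_rows],
            F=scale * calc.F[new_rows],
            sigF=np.zeros(np.sum(new_rows)),
            phi=calc.phi[new_rows],
            fom=np.full(np.sum(new_rows), ext_fom),
            measured=np.zeros(np.sum(new_rows), dtype=bool),
            cell=cell,
            spacegroup=sg,
        )
        out = ReflectionSet(
            np.concatenate([out.hkl, add.hkl]),
            np.concatenate([out.F, add.F]),
            np.concatenate([out.sigF, add.sigF]),
            np.concatenate([out.phi, add.phi]),
            np.concatenate([out.fom, add.fom]),
            None if out.hl is None else np.concatenate([out.hl, np.zeros((len(add), 4))]),
            np.concatenate([out.measured, add.measured]),
            cell,
            sg,
        ).sort()
    return out


def run_dm(
    refl: ReflectionSet,
    start_phases: ReflectionSet,
    cfg: DMConfig,
    reference: ReflectionSet | None = None,
):
    """Iterate map synthesis -> sphere variance -> modification -> inversion
    -> phase recombination for ``cfg.n_cycles``.

    Numerical scheme: a small held-out set of reflections (``free_fraction``,
    chosen from ``cfg.seed``) is excluded from every map synthesis and used
    to estimate the Fo/Fc agreement that weights the calculated phases, so
    the weight is not inflated by circularity.  The modification itself is
    applied with a relaxation step (``cfg.relaxation``), and the variance
    field is smoothed over ``cfg.variance_smoothing`` Angstroms before
    classification; both choices stabilise the fixed-point iteration, while
    flip/sharpen act exactly as printed on the full step.

    Measured amplitudes are never altered.  Returns ``(reflections with
    updated phases, last modified map, per-cycle diagnostics DataFrame)``.
    """
    from scipy.ndimage import gaussian_filter

    from .metrics import phase_error  # local import avoids a cycle

    cell, sg = refl.cell, refl.spacegroup
    d_min = float(np.min(refl.d[refl.measured]))
    grid = grid_for_resolution(cell, cfg.free_lunch_dmin or d_min, cfg.oversampling)

    # experimental phase distribution, held fixed across cycles
    experimental = refl.copy()
    ia, ib = experimental.match(start_phases)
    experimental.phi[:] = np.nan
    experimental.fom[:] = np.nan
    experimental.phi[ia] = start_phases.phi[ib]
    experimental.fom[ia] = start_phases.fom[ib]
    if start_phases.hl is not None:
        experimental.hl = np.zeros((len(experimental), 4))
        experimental.hl[ia] = start_phases.hl[ib]

    rng = np.random.default_rng(cfg.seed)
    free_flags = (rng.random(len(experimental)) < cfg.free_fraction) & experimental.measured
    free_set = {tuple(h) for h in experimental.hkl[free_flags]}

    working = experimental.copy()
    rows = []
    dm_map = None
    degenerate = cfg.solvent_fraction < 0.02 or cfg.solvent_fraction > 0.98
    for cycle in range(cfg.n_cycles):
        free = np.array([tuple(h) in free_set for h in working.hkl])
        syn = working.copy()
        syn.phi[free] = np.nan
        dmap = map_from_phases(syn, cell, sg, grid=grid, d_min=d_min)
        varmap = sphere_variance(dmap, cfg)
        if cfg.variance_smoothing > 0:
            sig_vox = cfg.variance_smoothing / dmap.spacing()
            varmap = VarianceMap(
                gaussian_filter(varmap.values, sigma=sig_vox, mode="wrap")
            )
        modified = modify_map(dmap, varmap, cfg)
        r = cfg.relaxation
        dm_map = DensityMap(
            (1.0 - r) * dmap.values + r * modified.values, cell, sg, d_min=dmap.d_min
        )
        inv_dmin = cfg.free_lunch_dmin or d_min
        calc = invert_map(dm_map, inv_dmin, hkl=working.hkl)
        d = cell.d_spacing(working.hkl)
        w_calc = _sigma_a_weights(working.F, calc.F, d, free, cfg.n_weight_bins)
        prior = _with_static_prior(experimental, working)
        working = combine_phases(prior, calc, w_calc=w_calc)
        if cfg.free_lunch_dmin is not None:
            working = free_lunch_extend(working, dm_map, cfg.free_lunch_dmin)
            experimental = _align_experimental(experimental, working)
        mean_fom = float(np.nanmean(working.fom))
        row = {
            "cycle": cycle + 1,
            "map_sigma": dmap.sigma,
            "mean_fom": mean_fom,
            "mean_w_calc": float(np.mean(w_calc)),
            "degenerate_solvent": degenerate,
        }
        if reference is not None:
            pc = phase_error(working, reference)
            row.update(
                {"mpe": pc.mpe, "wmpe": pc.wmpe, "mpe_centric": pc.mpe_centric, "wmpe_centric": pc.wmpe_centric}
            )
        rows.append(row)
        if mean_fom < 0.01:
            row["diverged"] = True
            break
    diagnostics = pd.DataFrame(rows)
    if dm_map is None:
        dm_map = map_from_phases(working, cell, sg, grid=grid, d_min=d_min)
    return working, dm_map, diagnostics


def _with_static_prior(experimental: ReflectionSet, working: ReflectionSet) -> ReflectionSet:
    """Experimental prior carried on the working index set (handles rows
    added by free-lunch extension, which carry no experimental phase)."""
    if len(experimental) == len(working) and np.array_equal(experimental.hkl, working.hkl):
        return experimental
    out = working.copy()
    out.phi[:] = np.nan
    out.fom[:] = np.nan
    ia, ib = out.match(experimental)
    out.phi[ia] = experimental.phi[ib]
    out.fom[ia] = experimental.fom[ib]
    if experimental.hl is not None:
        out.hl = np.zeros((len(out), 4))
        out.hl[ia] = experimental.hl[ib]
    else:
        out.hl = None
    return out


def _align_experimental(experimental: ReflectionSet, working: ReflectionSet) -> ReflectionSet:
    return _with_static_prior(experimental, working)
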