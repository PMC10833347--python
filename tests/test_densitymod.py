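import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasekit.densitymod import (
    DMConfig,
    VarianceMap,
    classify_voxels,
    combine_phases,
    default_nu,
    fibonacci_sphere,
    flip,
    free_lunch_extend,
    modify_map,
    run_dm,
    sharpen,
    sphere_variance,
)
from phasekit.maps import DensityMap, map_from_phases
from phasekit.reflections import ReflectionSet
from phasekit.symmetry import SpaceGroup, UnitCell

CELL = UnitCell(10.0, 12.0, 14.0)
P1 = SpaceGroup("P1")


class TestFlip:
    def test_printed_value(self):
        assert flip(0.5, 1.1) == pytest.approx(-0.55)

    def test_zero_fixed(self):
        assert flip(0.0, 1.1) == 0.0

    def test_gamma_one_is_involution(self):
        rho = np.linspace(-2, 2, 11)
        np.testing.assert_allclose(flip(flip(rho, 1.0), 1.0), rho)


class TestSharpen:
    def test_at_nu_sigma_gives_over_sqrt2(self):
        nu, sigma = 1.7, 0.3
        rho = nu * sigma
        assert sharpen(rho, nu, sigma) == pytest.approx(rho / np.sqrt(2.0))

    def test_large_rho_limit(self):
        nu, sigma = 2.0, 0.5
        rho = 100.0 * nu * sigma
        assert sharpen(rho, nu, sigma) / rho > 0.999

    def test_small_rho_limit(self):
        nu, sigma = 2.0, 0.5
        rho = 0.01 * nu * sigma
        assert sharpen(rho, nu, sigma) == pytest.approx(rho**2 / (nu * sigma), rel=1e-3)

    def test_negative_density_zeroed(self):
        assert sharpen(-1.0, 2.0, 0.5) == 0.0

    def test_nu_default_resolution_dependence(self):
        assert default_nu(1.0) > default_nu(2.0)
        assert 0.5 <= default_nu(10.0) <= default_nu(0.1) <= 5.0


class TestSphereVariance:
    def _smooth_map(self, seed=0, d_min=2.0, with_refl=False):
        rng = np.random.default_rng(seed)
        from phasekit.model import AtomicModel
        from phasekit.sfcalc import compute_structure_factors

        model = AtomicModel(["C"] * 6, rng.random((6, 3)), b=[12.0] * 6)
        rs = compute_structure_factors(model, CELL, P1, d_min)
        dmap = map_from_phases(rs, CELL, P1, d_min=d_min)
        return (dmap, rs) if with_refl else dmap

    def test_constant_map_zero_variance(self):
        dmap = DensityMap(np.full((16, 16, 16), 2.0), CELL, P1)
        var = sphere_variance(dmap, DMConfig())
        assert np.max(var.values) < 1e-12

    def test_translation_symmetry_of_1d_map(self):
        # map varying only along x: V must not depend on y or z
        nx, ny, nz = 20, 16, 16
        x = np.arange(nx) / nx
        vals = np.tile(np.cos(2 * np.pi * x)[:, None, None], (1, ny, nz))
        dmap = DensityMap(vals, CELL, P1)
        var = sphere_variance(dmap, DMConfig())
        spread = var.values.std(axis=(1, 2))
        assert np.max(spread) < 1e-10

    def test_fft_and_point_methods_agree(self):
        dmap = self._smooth_map()
        cfg = DMConfig()
        v1 = sphere_variance(dmap, cfg, method="fft").values
        v2 = sphere_variance(dmap, cfg, method="points").values
        # spectral vs trilinear sampling of the same Fibonacci set
        assert np.corrcoef(v1.ravel(), v2.ravel())[0, 1] > 0.99

    def test_matches_monte_carlo_oracle(self):
        """Variance at random voxels vs 10,000-point sphere sampling.

        A dense deterministic point set is used so the comparison measures
        the evaluation itself, not 92-point sampling noise; the oracle
        density is the exact Fourier sum at each sampling point."""
        dmap, rs = self._smooth_map(seed=1, with_refl=True)
        cfg = DMConfig(n_sphere_points=500)
        var = sphere_variance(dmap, cfg).values
        rng = np.random.default_rng(99)
        n = np.array(dmap.shape)
        # dense sampling: 10,000 quasi-uniform points under a random rotation
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(rng=rng).as_matrix()
        pts = fibonacci_sphere(10000) @ rot.T * cfg.sphere_radius
        coeffs = rs.F * np.exp(1j * np.radians(rs.phi))
        for _ in range(10):
            vox = rng.integers(0, n)
            centre = CELL.orthogonalize(vox / n)
            frac = CELL.fractionalize(centre + pts)
            rho = 2.0 * np.real(
                np.exp(-2j * np.pi * (frac @ rs.hkl.T)) @ coeffs
            ) / CELL.volume
            mc = float(np.var(rho))
            mine = var[tuple(vox)]
            assert mine == pytest.approx(mc, rel=0.05, abs=1e-6)

    def test_grid_coarser_than_radius_rejected(self):
        big_cell = UnitCell(40, 40, 40)
        dmap = DensityMap(np.zeros((8, 8, 8)), big_cell, P1)  # 5 A spacing
        with pytest.raises(ValueError, match="spacing"):
            sphere_variance(dmap, DMConfig())

    def test_fibonacci_points_on_unit_sphere(self):
        pts = fibonacci_sphere(92)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert np.linalg.norm(pts.mean(axis=0)) < 0.05  # quasi-uniform


class TestClassifyVoxels:
    def test_bimodal_map_split(self):
        v = np.concatenate([np.zeros(500), np.ones(500)]) + 1e-6
        var = VarianceMap(np.sort(v).reshape(10, 10, 10))
        w = classify_voxels(var, fs=0.5, band=0.10)
        assert np.all(w.ravel()[:450] == 0.0)
        assert np.all(w.ravel()[-450:] == 1.0)

    def test_solvent_fraction_recovered(self):
        rng = np.random.default_rng(0)
        var = VarianceMap(rng.random((12, 12, 12)))
        for fs in (0.3, 0.5, 0.7):
            w = classify_voxels(var, fs=fs, band=0.10)
            assert np.mean(w < 0.5) == pytest.approx(fs, abs=0.06)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_monotone_in_variance(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.random(4 * 4 * 4).reshape(4, 4, 4)
        w = classify_voxels(VarianceMap(v), fs=0.5)
        idx = np.unravel_index(np.argsort(v.ravel()), v.shape)
        ranked_w = w[idx]
        assert np.all(np.diff(ranked_w) >= -1e-12)


class TestModifyMap:
    def _map_and_var(self, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(10, 10, 10))
        dmap = DensityMap(vals, CELL, P1, d_min=2.0)
        var = sphere_variance(dmap, DMConfig())
        return dmap, var

    def test_all_protein_truncation_only(self):
        dmap, var = self._map_and_var()
        cfg = DMConfig(sharpen_weight=0.0)
        out = modify_map(dmap, var, cfg, weights=np.ones(dmap.shape))
        np.testing.assert_allclose(out.values, np.clip(dmap.values, 0, None))

    def test_all_solvent_pure_flip(self):
        dmap, var = self._map_and_var()
        cfg = DMConfig(gamma=1.1)
        out = modify_map(dmap, var, cfg, weights=np.zeros(dmap.shape))
        np.testing.assert_allclose(out.values, -1.1 * dmap.values)

    def test_output_between_pure_corrections(self):
        dmap, var = self._map_and_var(seed=3)
        cfg = DMConfig(sharpen_weight=0.5)
        out = modify_map(dmap, var, cfg).values
        solvent = flip(dmap.values, cfg.gamma)
        protein = modify_map(dmap, var, cfg, weights=np.ones(dmap.shape)).values
        lo = np.minimum(solvent, protein) - 1e-12
        hi = np.maximum(solvent, protein) + 1e-12
        assert np.all(out >= lo) and np.all(out <= hi)

    def test_nonnegative_map_fixed_point(self):
        rng = np.random.default_rng(5)
        vals = np.abs(rng.normal(size=(8, 8, 8)))
        dmap = DensityMap(vals, CELL, P1, d_min=2.0)
        var = VarianceMap(np.ones((8, 8, 8)))
        cfg = DMConfig(sharpen_weight=0.0, flip_only=False)
        out = modify_map(dmap, var, cfg, weights=np.ones(dmap.shape))
        np.testing.assert_allclose(out.values, vals)


class TestCombinePhases:
    def _sets(self, phi_exp, fom_exp, phi_calc, f=None):
        hkl = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0],
                        [2, 0, 0], [0, 2, 0], [0, 0, 2], [2, 1, 0],
                        [1, 2, 0], [1, 0, 2], [0, 1, 2], [2, 2, 0]])
        n = len(hkl)
        f = np.linspace(10, 4, n) if f is None else f
        exp = ReflectionSet(hkl, F=f, phi=np.full(n, phi_exp),
                            fom=np.full(n, fom_exp), cell=CELL, spacegroup=P1)
        calc = ReflectionSet(hkl, F=f * 1.01, phi=np.full(n, phi_calc),
                             fom=np.ones(n), cell=CELL, spacegroup=P1)
        return exp, calc

    def test_identical_phase_unchanged_fom_nondecreasing(self):
        exp, calc = self._sets(40.0, 0.6, 40.0)
        out = combine_phases(exp, calc)
        np.testing.assert_allclose(out.phi, 40.0, atol=1e-9)
        assert np.all(out.fom >= 0.6 - 1e-12)

    def test_zero_experimental_fom_gives_calc_phase(self):
        exp, calc = self._sets(10.0, 0.0, 130.0)
        out = combine_phases(exp, calc)
        np.testing.assert_allclose(out.phi, 130.0, atol=1e-9)

    def test_equal_weights_bisect(self):
        exp, calc = self._sets(0.0, 0.5, 90.0)
        out = combine_phases(exp, calc, w_calc=np.full(len(exp), 0.5))
        np.testing.assert_allclose(out.phi, 45.0, atol=1e-9)

    def test_amplitudes_pass_through(self):
        exp, calc = self._sets(0.0, 0.5, 90.0)
        out = combine_phases(exp, calc)
        np.testing.assert_array_equal(out.F, exp.F)

    def test_mismatched_cells_rejected(self):
        exp, calc = self._sets(0.0, 0.5, 90.0)
        calc.cell = UnitCell(11, 12, 14)
        with pytest.raises(ValueError, match="cell"):
            combine_phases(exp, calc)

    def test_hl_coefficients_drive_centroid(self):
        exp, calc = self._sets(0.0, 0.5, 90.0)
        exp.hl = np.zeros((len(exp), 4))
        exp.hl[:, 0] = 2.0  # concentration at phi=0
        out = combine_phases(exp, calc, w_calc=np.full(len(exp), 0.5))
        # calc at 90 deg pulls the centroid off zero but far less than 45 deg
        assert np.all(out.phi > 1.0) and np.all(out.phi < 45.0)


class TestFreeLunch:
    def test_identity_when_complete(self, small_fx):
        refl = small_fx["true"].copy()
        dmap = map_from_phases(refl, small_fx["cell"], small_fx["sg"], d_min=1.5)
        out = free_lunch_extend(refl, dmap, 1.5)
        np.testing.assert_array_equal(out.hkl, refl.sort().hkl)
        np.testing.assert_allclose(out.F, refl.sort().F)

    def test_extrapolated_amplitudes_correlate(self, small_fx):
        """Deleting 10% of reflections: the values filled from a clean
        *modified* map correlate strongly with the true amplitudes (the
        nonlinear modification is what generates off-support coefficients)."""
        true = small_fx["true"]
        rng = np.random.default_rng(17)
        drop = rng.random(len(true)) < 0.10
        kept = true.select(~drop)
        dmap = map_from_phases(kept, small_fx["cell"], small_fx["sg"], d_min=1.5)
        cfg = DMConfig(sharpen_weight=0.5)
        varmap = sphere_variance(dmap, cfg)
        dmap = modify_map(dmap, varmap, cfg)
        out = free_lunch_extend(kept, dmap, 1.5)
        ia, ib = out.select(~out.measured).match(true)
        ext = out.select(~out.measured)
        cc = np.corrcoef(ext.F[ia], true.F[ib])[0, 1]
        assert cc > 0.5
        # measured amplitudes bit-identical
        ja, jb = out.select(out.measured).match(kept)
        np.testing.assert_array_equal(out.select(out.measured).F[ja], kept.F[jb])


class TestRunDM:
    def test_zero_cycles_is_identity(self, medium_fx):
        cfg = DMConfig(n_cycles=0, seed=1)
        out, _, diag = run_dm(medium_fx["obs"], medium_fx["start"], cfg)
        ia, ib = out.match(medium_fx["start"])
        np.testing.assert_allclose(out.phi[ia], medium_fx["start"].phi[ib])
        assert len(diag) == 0

    def test_measured_amplitudes_never_altered(self, medium_fx):
        cfg = DMConfig(n_cycles=3, seed=1, free_lunch_dmin=1.8)
        out, _, _ = run_dm(medium_fx["obs"], medium_fx["start"], cfg)
        ia, ib = out.select(out.measured).match(medium_fx["obs"])
        np.testing.assert_array_equal(out.select(out.measured).F[ia],
                                      medium_fx["obs"].F[ib])

    @pytest.mark.parametrize("fs", [0.01, 0.99])
    def test_degenerate_solvent_fraction_runs(self, medium_fx, fs):
        cfg = DMConfig(n_cycles=1, solvent_fraction=fs, seed=1)
        out, _, diag = run_dm(medium_fx["obs"], medium_fx["start"], cfg)
        assert bool(diag["degenerate_solvent"].iloc[0])

    def test_perfect_phases_stay_accurate(self, medium_fx):
        """Density modification must not corrupt an already-correct
        phase set on clean data: wMPE stays under 10 degrees."""
        cfg = DMConfig(n_cycles=20, sharpen_weight=0.5, seed=1)
        out, _, diag = run_dm(
            medium_fx["obs"], medium_fx["true"], cfg, reference=medium_fx["true"]
        )
        assert diag["wmpe"].max() < 10.0


class TestHLStart:
    def test_run_dm_accepts_hl_coefficients(self, medium_fx):
        """Starting from a Hendrickson-Lattman-coded phase distribution
        runs through the HL combination path and keeps sane foms."""
        start = medium_fx["start"]
        kappa = np.clip(start.fom, 0, 0.95)
        kappa = kappa * (2 + 3 * kappa)  # crude concentration encoding
        hl = np.zeros((len(start), 4))
        hl[:, 0] = kappa * np.cos(np.radians(start.phi))
        hl[:, 1] = kappa * np.sin(np.radians(start.phi))
        hl_start = start.copy()
        hl_start.hl = hl
        cfg = DMConfig(n_cycles=2, sharpen_weight=0.5, seed=1)
        out, _, diag = run_dm(medium_fx["obs"], hl_start, cfg,
                              reference=medium_fx["true"])
        assert out.hl is not None
        assert np.all((out.fom[~np.isnan(out.fom)] >= 0)
                      & (out.fom[~np.isnan(out.fom)] <= 1))
        assert diag["wmpe"].iloc[-1] < 90.0
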