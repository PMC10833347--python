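import numpy as np
import pytest

from phasekit.geometry import dihedral, place_cb
from phasekit.maps import grid_for_resolution, map_from_phases
from phasekit.metrics import cc_fo_fc
from phasekit.resdata import AMINO_ACIDS
from phasekit.sidechain import (
    GammaAnnotation,
    SidechainConfig,
    MarkerSet,
    annotate_trace_for_phasing,
    apply_dock,
    build_sidechains,
    dock_sequence,
    error_correct,
    exclusion_mask,
    gamma_probe,
    residue_type_scores,
    secondary_structure_labels,
    stretch_cc_gate,
)
from phasekit.synthetic import SyntheticSpec, build_structure, make_trace, simulate_data
from phasekit.trace import Residue, Trace

DOCK_SEQUENCE = "MKVLFDAGYTSERWHINPQCVLKFDMGTAYSEWRHINPQG"


class TestPlaceCB:
    def test_matches_ccd_ideal_alanine(self):
        import biotite.structure.info as info

        res = info.residue("ALA")
        c = {n: res.coord[res.atom_name == n][0] for n in ("N", "CA", "C", "CB")}
        cb = place_cb(c["N"], c["CA"], c["C"])
        assert np.linalg.norm(cb - c["CB"]) < 0.05

    def test_bond_length_always_ideal(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n, ca, cc = rng.normal(size=(3, 3)) * 2.0
            if np.linalg.norm(np.cross(n - ca, cc - ca)) < 1e-3:
                continue
            cb = place_cb(n, ca, cc)
            assert np.linalg.norm(cb - ca) == pytest.approx(1.53, abs=1e-9)

    def test_l_chirality(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n, ca, cc = rng.normal(size=(3, 3)) * 3.0
            if np.linalg.norm(np.cross(n - ca, cc - ca)) < 1e-2:
                continue
            cb = place_cb(n, ca, cc)
            assert dihedral(n, ca, cc, cb) > 0

    def test_collinear_backbone_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            place_cb([0, 0, 0], [1, 0, 0], [2, 0, 0])


def _fixture_for(seq, seed=0, d_min=1.5):
    spec = SyntheticSpec(sequence=seq, fold="helix", spacegroup="P1", d_min=d_min)
    model, cell, sg, trace = build_structure(spec)
    true, obs = simulate_data(model, spec, cell, sg)
    dmap = map_from_phases(true, cell, sg, d_min=d_min)
    return model, cell, sg, trace, true, obs, dmap


class TestGammaProbe:
    def test_poly_valine_classified_branched(self):
        _, cell, sg, trace, *_, dmap = _fixture_for("VVVVVVVVVV")
        poly = make_trace(trace, 1.0, 0.0, seed=0)
        anns = gamma_probe(poly, dmap)
        frac = np.mean([a.cls == "BRANCHED" for a in anns[0]])
        assert frac >= 0.8

    def test_poly_glycine_classified_gly(self):
        _, cell, sg, trace, *_, dmap = _fixture_for("GGGGGGGGGG")
        poly = make_trace(trace, 1.0, 0.0, seed=0)
        anns = gamma_probe(poly, dmap)
        frac = np.mean([a.cls == "GLY" for a in anns[0]])
        assert frac >= 0.8

    def test_flat_map_gives_no_claims(self):
        from phasekit.maps import DensityMap

        _, cell, sg, trace, *_, dmap = _fixture_for("AVLSTGKDEF")
        flat = DensityMap(np.zeros(dmap.shape), cell, sg, d_min=1.5)
        poly = make_trace(trace, 1.0, 0.0, seed=0)
        anns = gamma_probe(poly, flat)
        assert all(a.cls in ("UNKNOWN", "GLY") for a in anns[0])

    def test_annotation_invariants(self):
        with pytest.raises(ValueError):
            GammaAnnotation("GLY", gamma_densities=(1.0, 2.0, 3.0))
        with pytest.raises(ValueError):
            GammaAnnotation("PSEUDO_SER", chi1=42.0)


class TestAnnotate:
    def test_all_gly_gives_pure_glycine_trace(self, dock_fx):
        trace = make_trace(dock_fx["trace"], 1.0, 0.0, seed=0)
        anns = [[GammaAnnotation("GLY") for _ in ch] for ch in trace.chains]
        model = annotate_trace_for_phasing(trace, anns, dock_fx["cell"])
        assert not np.isin(model.name, ("CB", "OG", "CG")).any()

    def test_occupancy_propagates_to_every_gamma_atom(self, dock_fx):
        trace = make_trace(dock_fx["trace"], 1.0, 0.0, seed=0)
        anns = gamma_probe(trace, dock_fx["map"])
        model = annotate_trace_for_phasing(trace, anns, dock_fx["cell"], occupancy=0.37)
        gam = np.isin(model.name, ("OG", "CG"))
        assert gam.any()
        assert np.all(model.occ[gam] == 0.37)
        assert np.all(model.occ[~gam] == 1.0)

    def test_gamma_atoms_change_fcalc(self, dock_fx):
        from phasekit.sfcalc import compute_structure_factors

        trace = make_trace(dock_fx["trace"], 1.0, 0.0, seed=0)
        anns = gamma_probe(trace, dock_fx["map"])
        with_g = annotate_trace_for_phasing(trace, anns, dock_fx["cell"])
        without = trace.to_model(dock_fx["cell"], polyalanine=True)
        fa = compute_structure_factors(with_g, dock_fx["cell"], dock_fx["sg"], 2.5).F
        fb = compute_structure_factors(without, dock_fx["cell"], dock_fx["sg"], 2.5).F
        assert not np.allclose(fa, fb)


class TestResidueTypeScores:
    def test_probabilities_normalised(self):
        for cls in ("GLY", "PSEUDO_SER", "PRO", "BRANCHED", "UNKNOWN"):
            scores = residue_type_scores(GammaAnnotation(cls))
            assert sum(np.exp(v) for v in scores.values()) == pytest.approx(1.0, abs=1e-9)

    def test_branched_favours_val_thr_ile(self):
        scores = residue_type_scores(GammaAnnotation("BRANCHED", chi1=180.0,
                                                     gamma_densities=(1, 1, 0)))
        best = max(scores, key=scores.get)
        assert best in ("V", "T", "I")

    def test_uniform_tables_give_equal_scores(self):
        flat_d = {cls: {aa: 1.0 / 20 for aa in AMINO_ACIDS}
                  for cls in ("GLY", "PSEUDO_SER", "PRO", "BRANCHED", "UNKNOWN")}
        flat_p = {lab: {aa: 1.0 / 20 for aa in AMINO_ACIDS} for lab in "HEC"}
        scores = residue_type_scores(GammaAnnotation("BRANCHED", chi1=180.0,
                                                     gamma_densities=(1, 1, 0)),
                                     density_table=flat_d, prior_table=flat_p)
        vals = list(scores.values())
        assert np.ptp(vals) < 1e-12

    def test_helix_labels_from_trace_geometry(self, dock_fx):
        labels = secondary_structure_labels(make_trace(dock_fx["trace"], 1.0, 0.0, seed=0))
        assert np.mean([l == "H" for l in labels[0]]) > 0.8


class TestDockSequence:
    def _dock_inputs(self, dock_fx, half_trace):
        anns = gamma_probe(half_trace, dock_fx["map"])
        return anns

    def _true_offset(self, dock_fx, half_trace):
        cas = np.array([r.ca for r in dock_fx["trace"].chains[0]])
        ca0 = half_trace.chains[0][0].ca
        return int(np.argmin(np.linalg.norm(cas - ca0, axis=1)))

    def test_register_recovered_and_matches_enumeration_oracle(self, dock_fx, half_trace):
        anns = self._dock_inputs(dock_fx, half_trace)
        dock = dock_sequence(half_trace, anns, DOCK_SEQUENCE)
        true_off = self._true_offset(dock_fx, half_trace)
        assert dock.offsets[0] == true_off
        assert dock.margins[0] >= 3.0
        # exhaustive enumeration oracle: naive rescoring of every offset
        from phasekit.sidechain import _score_matrix

        ss = secondary_structure_labels(half_trace)
        scores = _score_matrix(anns[0], ss[0])
        aa_idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        L, S = len(half_trace.chains[0]), len(DOCK_SEQUENCE)
        best_off, best_total = None, -np.inf
        for off in range(-2, S - L + 3):
            real = [(i, off + i) for i in range(L) if 0 <= off + i < S]
            if not real:
                continue
            vals = [scores[i, aa_idx[DOCK_SEQUENCE[j]]] for i, j in real]
            total = sum(vals) + (L - len(real)) * float(np.mean(vals))
            if total > best_total:
                best_total, best_off = total, off
        assert best_off == dock.offsets[0]

    def test_homopolymer_unassigned(self, dock_fx, half_trace):
        anns = self._dock_inputs(dock_fx, half_trace)
        dock = dock_sequence(half_trace, anns, "A" * 40)
        assert dock.offsets[0] is None
        assert dock.margins[0] < 3.0

    def test_sequence_shorter_than_chain_is_diagnosed(self, dock_fx, half_trace):
        anns = self._dock_inputs(dock_fx, half_trace)
        dock = dock_sequence(half_trace, anns, "MKV")
        assert dock.offsets[0] is None
        assert any("unassigned" in d or "longer" in d for d in dock.diagnostics)

    def test_marker_strictly_increases_margin(self, dock_fx, half_trace):
        """A selenium marker at the methionine site anchors the register."""
        anns = self._dock_inputs(dock_fx, half_trace)
        true_off = self._true_offset(dock_fx, half_trace)
        # place the marker at the true Met SD-ish position: the residue in
        # the traced window whose true identity is M
        window = DOCK_SEQUENCE[true_off : true_off + len(half_trace.chains[0])]
        if "M" not in window:
            pytest.skip("traced window carries no methionine")
        i = window.index("M")
        res = half_trace.chains[0][i]
        from phasekit.sidechain import _expected_sulfur_site

        site = _expected_sulfur_site(res, "M")[0]
        markers = MarkerSet(site[None, :], ["SE"])
        bare = dock_sequence(half_trace, anns, DOCK_SEQUENCE)
        with_m = dock_sequence(half_trace, anns, DOCK_SEQUENCE, markers=markers)
        assert with_m.offsets[0] == true_off
        assert with_m.margins[0] > bare.margins[0]

    def test_permutation_stable(self, dock_fx):
        trace = make_trace(dock_fx["trace"], 1.0, 0.0, seed=0)
        # split into two chains of different length
        c = trace.chains[0]
        t1 = Trace([c[:25], c[25:]], validate_geometry=False)
        t2 = Trace([c[25:], c[:25]], validate_geometry=False)
        a1 = gamma_probe(t1, dock_fx["map"])
        a2 = gamma_probe(t2, dock_fx["map"])
        d1 = dock_sequence(t1, a1, DOCK_SEQUENCE)
        d2 = dock_sequence(t2, a2, DOCK_SEQUENCE)
        assert d1.offsets == list(reversed(d2.offsets))


class TestErrorCorrect:
    def test_clean_trace_untouched(self, dock_fx):
        clean = make_trace(dock_fx["trace"], 1.0, 0.0, seed=0)
        out = error_correct(clean, dock_fx["map"])
        assert out.n_residues == clean.n_residues and len(out) == len(clean)

    def test_displaced_residue_cut_exactly_once(self, dock_fx):
        clean = make_trace(dock_fx["trace"], 1.0, 0.0, seed=0)
        bad = Trace([[r.copy() for r in c] for c in clean.chains],
                    validate_geometry=False)
        shift = np.array([0.0, 6.0, 6.0])
        shift = shift / np.linalg.norm(shift) * 3.0
        for a in bad.chains[0][20].atoms:
            bad.chains[0][20].atoms[a] = bad.chains[0][20].atoms[a] + shift
        out = error_correct(bad, dock_fx["map"])
        assert len(out) == 2  # one cut
        assert out.n_residues == bad.n_residues  # no residue dropped here

    def test_empty_trace_passthrough(self, dock_fx):
        out = error_correct(Trace([]), dock_fx["map"])
        assert out.n_residues == 0

    def test_idempotent(self, dock_fx):
        trace = make_trace(dock_fx["trace"], 1.0, 0.3, seed=5)
        once = error_correct(trace, dock_fx["map"])
        twice = error_correct(once, dock_fx["map"])
        assert twice.n_residues == once.n_residues and len(twice) == len(once)


class TestBuildAndGate:
    def test_polyala_dock_is_identity(self, dock_fx, half_trace):
        anns = gamma_probe(half_trace, dock_fx["map"])
        dock = dock_sequence(half_trace, anns, "A" * 40)  # unassigned
        model = build_sidechains(half_trace, dock, dock_fx["map"], "A" * 40,
                                 dock_fx["cell"])
        poly = half_trace.to_model(dock_fx["cell"], polyalanine=True)
        assert len(model) == len(poly)

    def test_built_sidechains_sit_in_density(self, dock_fx, half_trace):
        from phasekit.maps import interpolate_density

        anns = gamma_probe(half_trace, dock_fx["map"])
        dock = dock_sequence(half_trace, anns, DOCK_SEQUENCE)
        assert dock.offsets[0] is not None
        model = build_sidechains(half_trace, dock, dock_fx["map"], DOCK_SEQUENCE,
                                 dock_fx["cell"])
        side = ~np.isin(model.name, ("N", "CA", "C", "O", "CB"))
        pos = model.xyz_orth(dock_fx["cell"])[side]
        mean_rho = float(np.mean(interpolate_density(dock_fx["map"], pos)))
        assert mean_rho > dock_fx["map"].sigma

    def test_atom_counts_match_residue_types(self, dock_fx, half_trace):
        anns = gamma_probe(half_trace, dock_fx["map"])
        dock = dock_sequence(half_trace, anns, DOCK_SEQUENCE)
        docked = apply_dock(half_trace, dock, DOCK_SEQUENCE, dock_fx["map"])
        expected = {"TRP": 14, "PHE": 11, "SER": 6, "VAL": 7, "GLY": 4, "ALA": 5}
        for chain in docked.chains:
            for res in chain:
                if res.name in expected:
                    assert len(res.atoms) == expected[res.name], res.name

    def test_gate_keeps_correct_sidechains(self, dock_fx, half_trace):
        anns = gamma_probe(half_trace, dock_fx["map"])
        dock = dock_sequence(half_trace, anns, DOCK_SEQUENCE)
        docked = apply_dock(half_trace, dock, DOCK_SEQUENCE, dock_fx["map"])
        gated = stretch_cc_gate(docked, dock_fx["obs"], dock_fx["cell"], dock_fx["sg"])
        n_side = sum(len(r.atoms) for c in gated.chains for r in c)
        n_before = sum(len(r.atoms) for c in docked.chains for r in c)
        assert n_side == n_before  # correct side chains survive the gate

    def test_gate_reverts_wrong_sidechains(self, dock_fx, half_trace):
        anns = gamma_probe(half_trace, dock_fx["map"])
        dock = dock_sequence(half_trace, anns, DOCK_SEQUENCE)
        docked = apply_dock(half_trace, dock, DOCK_SEQUENCE, dock_fx["map"])
        # rotate every side chain into solvent: swap in garbage coordinates
        rng = np.random.default_rng(8)
        for res in docked.chains[0]:
            for a in list(res.atoms):
                if a not in ("N", "CA", "C", "O", "CB"):
                    res.atoms[a] = res.atoms[a] + rng.normal(0, 4.0, 3)
        gated = stretch_cc_gate(docked, dock_fx["obs"], dock_fx["cell"], dock_fx["sg"])
        kept = sum(1 for r in gated.chains[0]
                   if set(r.atoms) - {"N", "CA", "C", "O", "CB"})
        assert kept == 0

    def test_gate_identity_without_sidechains(self, dock_fx, half_trace):
        out = stretch_cc_gate(half_trace, dock_fx["obs"], dock_fx["cell"], dock_fx["sg"])
        assert out.n_residues == half_trace.n_residues

    def test_gate_never_lowers_full_model_cc(self, dock_fx, half_trace):
        anns = gamma_probe(half_trace, dock_fx["map"])
        dock = dock_sequence(half_trace, anns, DOCK_SEQUENCE)
        docked = apply_dock(half_trace, dock, DOCK_SEQUENCE, dock_fx["map"])
        before = cc_fo_fc(docked.to_model(dock_fx["cell"], polyalanine=False),
                          dock_fx["obs"], dock_fx["cell"], dock_fx["sg"])
        gated = stretch_cc_gate(docked, dock_fx["obs"], dock_fx["cell"], dock_fx["sg"])
        after = cc_fo_fc(gated.to_model(dock_fx["cell"], polyalanine=False),
                         dock_fx["obs"], dock_fx["cell"], dock_fx["sg"])
        assert after >= before - 1e-9


class TestExclusionMask:
    def test_empty_model_empty_mask(self, dock_fx):
        from phasekit.model import AtomicModel

        model = AtomicModel(["C"], [[0, 0, 0]]).select([False])
        grid = grid_for_resolution(dock_fx["cell"], 2.0)
        mask = exclusion_mask(model, grid, dock_fx["cell"], dock_fx["sg"], 2.0)
        assert not mask.any()

    def test_single_atom_sphere_volume(self, dock_fx):
        from phasekit.model import AtomicModel

        cell = dock_fx["cell"]
        model = AtomicModel(["C"], [[0.5, 0.5, 0.5]])
        grid = grid_for_resolution(cell, 2.0)
        radius = 2.0
        mask = exclusion_mask(model, grid, cell, dock_fx["sg"], radius)
        expected = (4.0 / 3.0) * np.pi * radius**3 / cell.volume
        assert mask.mean() == pytest.approx(expected, rel=0.2)

    def test_masked_trace_probes_unknown(self, dock_fx, half_trace):
        mask = np.ones(dock_fx["map"].shape, dtype=bool)
        anns = gamma_probe(half_trace, dock_fx["map"], mask=mask)
        assert all(a.cls == "UNKNOWN" for ch in anns for a in ch)


class TestSequenceCopies:
    def test_fasta_copy_count_bounds_docked_chains(self, dock_fx):
        """With NCS, one sequence copy per chain: a single copy docks only
        the best chain even when two chains would both match."""
        trace = make_trace(dock_fx["trace"], 1.0, 0.0, seed=0)
        c = trace.chains[0]
        two = Trace([c[:20], c[20:]], validate_geometry=False)
        anns = gamma_probe(two, dock_fx["map"])
        unbounded = dock_sequence(two, anns, DOCK_SEQUENCE)
        n_free = sum(o is not None for o in unbounded.offsets)
        if n_free < 2:
            pytest.skip("fixture does not dock both chains")
        cfg = SidechainConfig(max_docked_chains=1)
        bounded = dock_sequence(two, anns, DOCK_SEQUENCE, cfg=cfg)
        assert sum(o is not None for o in bounded.offsets) == 1
        assert any("copies exhausted" in d for d in bounded.diagnostics)
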