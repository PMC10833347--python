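# Methods

This note documents the models, numerical choices and limitations behind
phasekit. It states nothing the test suite or `scripts/acceptance.py`
does not itself compute.

## Crystallographic substrate

All internal coordinates are fractional; PDB input/output converts with
the standard orthogonalisation matrix (a along x, b in the x–y plane).
Structure factors follow the convention
ρ(x) = (1/V) Σ_h F(h) e^{−2πi h·x}, F = |F| e^{iφ}, so an atom at
fractional (0.5, 0, 0) carries φ(100) = 180°. Amplitudes are computed by
direct summation over symmetry-expanded atoms with the bundled 4-Gaussian
IT92 form-factor table (C, N, O, S, Se, H, and a mercury-coefficient
generic heavy atom), isotropic B attenuation exp(−B s²) with
s = 1/(2d), and occupancy scaling. Four space groups are supported — P1,
P2₁, P2₁2₁2₁, P4₃2₁2 — with operator data taken from gemmi's tables and
the allowed-origin-shift set derived from the condition (R−I)t ∈ Z for
every operator; polar directions are detected from the common null space.
Unique reflections are stored one per orbit in the hemisphere l > 0 (tie
broken towards l = 0, k > 0, then h ≥ 0, lexicographically largest),
systematic absences removed.

Map synthesis places m·F coefficients (m = 1 where no figure of merit is
given) for all symmetry- and Friedel-equivalents on an FFT grid with
spacing ≤ d_min/4 (configurable; dimensions are multiples of 4 so screw
translations land on grid points), and map inversion is the forward FFT.
Density interpolation is periodic cubic-spline by default: plain trilinear
interpolation at 4× oversampling misses density peaks by up to a quarter
of the map σ, cubic stays well under a percent (a trilinear path remains
available via `order=1`).

## Sphere-of-influence density modification

Per cycle: synthesise the working map → classify voxels by the variance of
the density on the 2.42 Å spherical surface around each voxel → apply the
modification → invert → recombine phases with the starting distribution.

* **Sphere variance.** The surface is sampled at 92 deterministic
  Fibonacci-lattice points (configurable). The point-set mean is evaluated
  through Fourier phase shifts — exact for the band-limited map — and the
  mean of ρ² on a spectrally zero-padded 2× grid, where ρ² is itself
  band-limited, so the computed variance is exact for the trigonometric
  interpolant. A direct trilinear sampling path (`method="points"`)
  cross-checks it. Before classification the variance field is smoothed
  with a 0.75 Å Gaussian: the raw field is noise-dominated at large phase
  errors and the smoothing stabilises the solvent mask without moving its
  quantiles.
* **Classification.** Voxels are ranked by variance; the lowest
  `fs − band/2` fraction is solvent (w_p = 0), the highest
  `1 − fs − band/2` protein (w_p = 1), with a linear crossover over
  `band` = 10% of voxels. There is deliberately no explicit boundary.
* **Modification.** Solvent: ρ′ = −γρ, γ = 1.1. Protein: truncation at
  zero blended (weight `sharpen_weight`, default 1.0 for experimental
  phases, 0.5 recommended for fragment-derived phases) with
  ρ_mod = [ρ⁴/(ν²σ²+ρ²)]^½, where σ is the global map standard deviation
  and ν = 2.5/d_min clamped to [0.5, 5] (larger at higher resolution).
  These formulas are implemented exactly and spot-checked analytically.
  The full modification is then applied as a relaxed step,
  ρ ← (1−r)ρ + r·modified, r = 0.7 by default. The flip is an aggressive,
  non-convex reflector; taken full-step on an imperfect solvent mask the
  iteration diverges, while the relaxed step converges monotonically —
  the standard situation for alternating-projection schemes.
* **Recombination.** 7% of the measured reflections are held out of every
  map synthesis and the Fo/Fc correlation of the modified map is estimated
  per resolution bin on this free set only; an in-synthesis correlation is
  inflated by circularity (the map was built from the very amplitudes it
  is compared against) and stalls the iteration at the starting phases.
  The binned correlation enters a σ_A-style per-reflection weight,
  m = I₁(X)/I₀(X), X = 2σ_A E_o E_c/(1−σ_A²), so strong normalised
  amplitudes carry more phase trust. The calculated phase vector is summed
  with the starting phase vector (weight = starting figure of merit) and
  renormalised; when Hendrickson–Lattman coefficients are supplied the
  calculated phase enters as an (A, B) increment and the centroid of the
  updated distribution is returned. Measured amplitudes are never altered.
* **Free lunch.** Optionally, unmeasured reflections (interior gaps or
  beyond the resolution limit) are filled with scaled amplitudes and
  phases from the modified map, flagged extrapolated, and given a damped
  figure of merit; the nonlinear modification is what creates information
  at these indices.

## Map interpretation

* **Gamma probing.** Each traced residue gets an ideal tetrahedral CB
  (|CA–CB| = 1.53 Å, positive improper N-CA-C-CB torsion — validated
  against the CCD ideal alanine to < 0.05 Å). If the CB density is below
  0.5σ the residue is a probable glycine. Otherwise density is probed
  1.47 Å from CB at the three staggered χ₁ rotamers: an insignificant
  spread (< 1.0σ) is UNKNOWN; a non-trans maximum triggers the ±30°
  proline-geometry probe; a near-tie of the top two values (within 0.25σ,
  both clearly above the minimum) is BRANCHED (Val/Thr/Ile-like); the
  rest are pseudo-serine, modelled with a gamma O at the slightly longer
  1.52 Å. Thresholds are expressed in units of map σ so they transfer
  across resolutions; all are configurable. Annotated gamma atoms join the
  phasing model at occupancy 0.6.
* **Sequence docking.** Chains are processed longest first. For every
  sliding offset (two dummy residues of overhang per end) the score is the
  sum of per-residue log-probabilities: a bundled compatibility table
  P(annotation class | residue type) times a Chou–Fasman-style secondary
  structure prior, with the trace's own geometry (CA pseudo-torsion ≈ 50°
  helix, ≈ ±170° strand) supplying the labels. Dummy positions contribute
  the mean per-residue score of the real window so offsets of different
  overhang are comparable. A Cys/Met (S) or Met (Se) assignment whose
  expected sulfur position falls within 2.5 Å of a supplied marker earns
  +4 log units; a stranded marker costs 2. An offset is accepted only if
  it beats the runner-up by ≥ 3 log units ("distinctly better");
  sequence ranges claimed by earlier chains are blocked.
* **Error correction.** The connection between residues i and i+1 is
  characterised by (ψᵢ, φᵢ₊₁) against a generous box-union Ramachandran
  mask (α, β/PPII and left-handed-α basins) and cut only when its mean
  backbone density is also strictly below both flanking connections'.
  The strictness makes a single displaced residue produce exactly one cut.
  Chains split at cuts; single residues are dropped. The operation is
  idempotent.
* **Side-chain building and gating.** Docked residues are built from a
  small ideal-geometry rotamer set (most common rotamer per χ₁ well,
  NeRF internal-coordinate placement), choosing the rotamer with the best
  mean density. Per stretch (chain), side chains are kept only if the
  whole-model amplitude correlation does not drop when they are included.
* **The driver.** `run_extension` alternates density-modification blocks
  with interpretation cycles. Trace-derived phases are combined into the
  current state with the σ_A weights — but each structurally new model
  only once: recombining an unchanged model every cycle double-counts its
  information and drags the phases back toward it. The first cycle and a
  newly successful docking count as new information; once the model has
  converged the loop stops, since further cycles would recompute the same
  state. The polyalanine-trace CC gates docking at 30% and the solved
  verdict at 25%, and is always reported separately from the full-model
  CC. With docking requested but no sequence available the driver warns
  and continues in gamma-only mode.

## Metrics

MPE is the mean minimal absolute phase difference in degrees (90° is the
random expectation), wMPE weights by the reference figure of merit, and
centric reflections (some operator maps h → −h) are reported separately.
`reconcile_phases` exhausts the allowed origin shifts × inversion through
the group's candidate centres (non-origin centres are representable),
refines continuous polar components by grid search plus Nelder–Mead, and
returns the shift it applied to the test set; it never leaves the wMPE
above the identity transform. The amplitude correlation `cc_fo_fc` is the
Pearson correlation of resolution-bin-normalised amplitudes (E-like),
reported as a percentage: raw-F correlation scores even a random-atom
model above 50% through the shared radial falloff, normalisation puts the
null near zero and the true model at 100.

## Synthetic crystals

The generator builds ideal-geometry folds (α-helix φ/ψ = −57/−47, strand
−120/+120, or an antiparallel helix pair 11.5 Å apart) with full side
chains from the rotamer table, aligns the long axis with the screw axis
where there is one, and pads an orthorhombic-ish cell until an atom-mask
volume calculation hits the target solvent fraction (achieved within 5%);
the molecular origin is then grid-searched for maximal symmetry-mate
clearance and packing is verified. Observed amplitudes are the true ones
with multiplicative Gaussian noise (default 2%). Starting phases are the
truth plus wrapped-normal noise whose width varies per reflection —
proportional to 1/d and scattered lognormally (σ = 0.6) — with the
overall scale solved by bisection so the realised error matches the
requested wMPE to a fraction of a degree, and per-reflection figures of
merit set to the expected cosine exp(−σᵢ²/2). The heterogeneity matters:
a start in which every reflection is equally unreliable corresponds to no
physical phasing experiment and gives density modification no reliable
subset to build from. Partial traces keep a contiguous stretch of
residues as polyalanine and jitter atoms by a Gaussian displacement
(redrawn if the CA–CA envelope breaks).

What the fixtures do not emulate: bulk solvent (the solvent is vacuum, so
its true density is featureless by construction — flattening is a weaker
constraint on real data), measurement incompleteness, anisotropy,
radiation damage, twinning, and model bias from molecular-replacement
search models. Passing tests demonstrate the machinery is internally
correct and effective under clean conditions, not performance parity with
production phasing programs on deposited data.

## Problem sizes and determinism

The packaged fixtures are a 10-residue helix in P1 at 1.5 Å (~1600
reflections) and a 30-residue helix pair in P2₁ at 2.0 Å (~2200
reflections, ~56×64×56 grid); these sizes keep a full 10-seed
density-modification experiment and the complete test suite within a few
minutes on one CPU while leaving every stage non-trivial. Density
modification itself uses no randomness beyond the seed-derived free-set
choice; identical seeds give byte-identical diagnostic files.

## Known limitations

De novo main-chain autotracing is out of scope — traces are inputs — so
the interpretation loop converges quickly instead of growing the model;
exhaustive side-chain enumeration, NCS averaging, histogram matching,
maximum-likelihood density modification, anisotropic/anomalous scattering
models and refinement are likewise not implemented. The supported
space-group set is the minimal one exercising triclinic, polar
monoclinic, primitive orthorhombic and tetragonal enantiomorphic cases.
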