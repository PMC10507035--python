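# Methods

## Overview

`viscaselect` selects, from a large library of candidate protein
conformations (typically MD snapshots), the ensemble that best explains
a set of polarized vibrational sum-frequency generation (VSFG) amide-I
spectra recorded at a lipid–water interface. The chain is:

1. map each structure frame onto amide-I chromophores,
2. build and diagonalize a one-exciton Hamiltonian,
3. convert the eigenmodes into azimuthally averaged χ⁽²⁾ elements and
   polarized intensities (SSP, PPP, SPS, PSP),
4. score each frame against the experimental spectra by a residual sum
   of squares (RSS) after a single fitted scale,
5. grow the ensemble in ascending-RSS order until its spectral spread
   matches the experimental standard deviation,
6. characterize the selected ensemble structurally (simplified-DSSP
   helicity, per-residue minimum lipid distance, segment summaries).

## Exciton model

Each peptide bond contributes one local oscillator. The transition
dipole lies in the O=C–N plane, rotated `dipole_tilt_deg` (default 20°)
from the C=O bond toward the nitrogen, anchored `anchor_offset`
(default 0.868 Å) from the carbonyl carbon along C=O. The local Raman
tensor is axially symmetric about the dipole with principal values
(1, ρ, ρ), ρ = `raman_ratio` (default 0.25). Local frequencies are a
uniform `omega0` (default 1650 cm⁻¹, amide-I′ in a D₂O subphase);
per-unit shifts can be supplied externally (there is deliberately no
built-in electrostatic frequency map). Couplings:

- |i−j| = 1 within a chain: constant `nn_coupling` (default −8.5 cm⁻¹),
  with a hook for a (φ,ψ)-map callable;
- otherwise point transition-dipole coupling
  J = A·[ê_i·ê_j − 3(ê_i·n̂)(ê_j·n̂)]/r³ with prefactor
  `coupling_prefactor` A = 580 cm⁻¹·Å³ for unit dipoles, giving
  non-neighbour couplings of a few cm⁻¹ at typical backbone distances.

All of these are conventions of the widely used amide-I
parameterizations and are exposed in the configuration; none is a
fitted quantity. Proline amides are retained with identical parameters
and flagged. Chain breaks (C–N > 2.5 Å) interrupt the chromophore
chain. Diagonalization uses a dense symmetric eigensolver; collective
dipoles and Raman tensors are eigenvector contractions, so trace and
dipole-strength sum rules hold to rounding and are asserted in tests.

## χ⁽²⁾ and polarized intensities

The frame hyperpolarizability is

    β_abc(ω) = Σ_q A_q,ab · M_q,c / (ω_q − ω − iΓ/2),

a complex Lorentzian per mode with Γ = `linewidth_fwhm` (default
12 cm⁻¹, the FWHM of the single-mode |χ|² peak). Azimuthal averaging
about the interface normal (C∞v monolayer symmetry) is numeric over
`n_phi` uniform rotations (default 36) or closed-form (`n_phi = 0`);
because the integrand is a trigonometric polynomial of degree three,
any equispaced rule with ≥ 4 points is already exact and the two paths
agree to rounding. Surviving elements obey χ_xxz = χ_yyz,
χ_xzx = χ_yzy, χ_zxx = χ_zyy and the chiral antisymmetry
χ_xyz = −χ_yxz.

Intensities: I_SSP ∝ |w·χ_yyz|², I_SPS ∝ |w·χ_yzy|², I_PPP the squared
modulus of a four-element combination (xxz, xzx, zxx, zzz), and the
chiral I_PSP from (xyz, zyx). Fresnel/local-field weights default to
unity and are configuration-exposed: the selection compares relative
lineshapes and inter-PC ratios after a fitted scale, so the weights are
conventions, not fixed physical claims; the same holds for the optional
constant non-resonant background (default zero). Frequency-dependent
Fresnel dispersion and heterodyne phase are out of scope.

Frame averaging supports two semantics: `intensity` (incoherent mean of
|χ|², independent interface patches) and `susceptibility` (coherent
mean of χ then squared, molecules in one patch), matching the physical
distinction that coherent averaging lets opposite-phase contributions
interfere destructively.

## Frame selection

For each frame a single non-negative scale s minimizing
Σ_PC Σ_ω (I_exp − s·I_calc)² is fitted jointly across the included
polarization combinations (closed form, clamped at zero), preserving
inter-PC ratios; RSS is the post-scale residual sum over the scoring
window. Defaults: window 1600–1700 cm⁻¹ (the amide-I band only — the
lipid ester carbonyl near 1730 cm⁻¹ is not simulated), all four PCs at
unit weight including PSP (whose inclusion filters frames with spurious
chiral response). Ranking is ascending RSS with ties broken by global
frame index.

The ensemble cutoff matches spread to spread: members are added in rank
order until the pooled standard deviation of the scaled member spectra
first reaches the pooled experimental standard deviation. Pooling is
the mean of per-point sample standard deviations (n−1 denominator) over
the scored window and PCs, on both sides of the comparison; this is the
simplest symmetric pooling and is a documented choice, since only the
matching criterion itself — not the pooling — is canonical. A zero
experimental spread selects the rank-1-tied frames. The threshold
reported is the RSS of the last included member; the per-PC mean and
min/max envelopes of the members are part of the result.

A consequence worth knowing: if the experimental noise exceeds the
spectral diversity of the structures that genuinely fit the data, the
first-crossing rule must walk past them into poorer-fitting structures
before the spread criterion is met. The method therefore presumes
high signal-to-noise data whose replicate spread is comparable to, or
below, the within-ensemble spectral variation.

Orientation scans score a rigid structure on a (tilt, twist) grid:
twist about the molecular z axis first, then tilt about a horizontal
lab axis, both about the centroid. Order matters: a lab-frame azimuth
is invisible to azimuthally averaged spectra, so the twist must select
the interface-facing side *before* tilting; with this convention the
tilt-0 row of the RSS map is constant and the map is 360°-periodic in
twist.

## Ensemble analysis

Secondary structure is the simplified three-state DSSP: Kabsch–Sander
hydrogen-bond energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
kcal/mol, bond if E < −0.5; 3/4/5-turn patterns yield helix states and
parallel/antiparallel bridge patterns yield strand, collapsed to
{H, E, C} (α/3₁₀/π → H; bridge/ladder → E, without the isolated-bridge
distinction, which the 3-state collapse erases anyway). Missing amide
hydrogens are placed 1.01 Å from N along the preceding C=O direction;
chain-start and proline nitrogens do not donate. The implementation is
validated against an independent reference (mdtraj's simplified DSSP)
at ≥ 95% per-residue agreement on helix/sheet/coil fixtures.

Lipid proximity is the per-residue minimum distance over **all** residue
atoms (not only backbone — a documented choice) to any lipid atom,
computed with an exact KD-tree nearest-neighbour query and verified
against the O(N²) double loop. Profiles report the mean and the
standard error of the mean (member std/√N) over ensemble members.
Default segment summaries use the α-synuclein regions: N-terminal 1–60,
NAC 61–95, C-terminal 96–140.

## Synthetic data generator

The generator emulates the two inputs of the workflow:

- **Structures**: poly-alanine N/CA/C/O/H backbones from ideal internal
  coordinates at chosen (φ, ψ) via natural-extension placement; ideal
  helices (−57°, −47°; rise ≈ 1.5 Å/residue) are canonically aligned
  with +z (N-terminus down) and then tilted/twisted/translated. Coils
  draw dihedrals from a broad PPII/extended basin (φ ∈ [−180, −50];
  ψ ∈ [60, 180] ∪ [−180, −150]), seeded. The membrane is a square grid
  of phosphorus-like beads (residue DPPG) — a purely geometric stand-in
  with no lipid chemistry, adequate for distance and orientation
  analysis only.
- **Spectra**: a known mixture of calculated frame intensities plus
  i.i.d. Gaussian per-point noise (homoscedastic per PC) over 2–50
  replicates, from which the dataset mean and per-point sample standard
  deviation are formed exactly as for real replicate series.

The flat-vs-upright benchmark builds 200 frames above one slab: 35%
flat helices (tilt 80–100°), 35% upright helices (tilt 0–20°,
N-terminus at the slab), 30% coils, each with 3° Gaussian dihedral
jitter, uniform twist, and 4–6 Å clearance. Reference datasets are
generated from 15-frame uniform mixtures of one class with 30
replicates and noise at 1% of the mixture's SSP peak — the high
signal-to-noise regime replicate-averaged VSFG data occupy, and
deliberately anchored to the dataset's own signal level rather than to
any single frame, whose intensity can be orders of magnitude off the
mixture's. Everything is a pure function of (specification, seed).

What passing the benchmark does and does not show: it demonstrates that
orientation classes with well-separated spectra are recovered at high
purity by RSS ranking plus the std-matched cutoff, with disjoint
ensembles across conditions and the expected lipid-distance signature.
It does not demonstrate performance on real data, where conformational
heterogeneity is continuous rather than clustered, local frequencies
are site-dependent, Fresnel factors are not unity, and noise is
correlated across frequency.

## Numerical choices and degenerate inputs

- Chain-break cutoff 2.5 Å (C–N); chromophores are not built across
  breaks.
- TDC below 0.5 Å separation raises a geometry error (clash).
- All-zero calculated spectra fit scale 0 with a warning; empty mode
  sets give a zero spectrum with a warning.
- An ensemble whose spread never reaches the experimental spread
  selects all frames and warns.
- Selection, ranking and generators are deterministic given inputs and
  seed; parallel spectra evaluation is bit-identical to serial.

## Chirality of ideal fixtures

Single ideal helices are chiral-VSFG silent in this model (PSP below
10⁻⁶ of the strongest SSP over the whole tilt family). Near 90° tilt
the achiral response of the ideal helix also collapses — under the
20°-toward-N dipole convention the transition dipoles sit only ~8° off
the helix axis, so a flat helix has almost no z-projected dipole
strength — which makes a per-orientation chiral-to-achiral ratio
ill-posed there; ratios are therefore asserted per orientation where
achiral signal exists and at family level overall. A *single* coil
conformer is genuinely chiral at the level of its dipole arrangement
(PSP/SSP ~ 0.1); the chiral silence of disordered structures is an
ensemble property, realized here as a handedness-balanced coherent
average (each conformer with its mirror image), which cancels the
chiral elements exactly while retaining achiral signal — and doubles as
a check of the reflection symmetry of the tensor machinery. A
hydrogen-bonded two-strand (sheet-like) fixture, by contrast, has a
measurably nonzero PSP.

## Problem sizes

Tests and the acceptance script run the benchmark at 200 frames of
30-residue structures on a 101-point grid, orientation scans at
5°/10° steps for a 30-residue helix, and Monte-Carlo isotropy checks at
10⁴ rotations; these sizes give sub-minute runtimes while leaving all
statistical margins wide (purity margins ≥ 10 percentage points,
Monte-Carlo 3σ bands).

## Known limitations

- No electrostatic/dihedral frequency maps, two-exciton states, isotope
  labels, or anharmonicity.
- Uniform local frequency makes absolute band positions only as good as
  `omega0`; selection relies on relative lineshapes and PC ratios.
- Unity Fresnel weights are a convention; absolute inter-PC ratios
  should not be over-interpreted.
- The pseudo-lipid slab cannot test chemistry-specific binding, only
  geometry.
- Hard-threshold selection as specified; no Bayesian or
  maximum-entropy reweighting.
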