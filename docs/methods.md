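# Methods

## Model and scope

The package analyses trajectories of lattice assemblies built from a
two-monomer repeating subunit (the αβ-tubulin heterodimer): per-subunit
collective motions by covariance analysis of a pooled, superposed subunit
ensemble; filament bending by monomer-center geometry; and single-particle
relaxation by van Hove / intermediate-scattering functions. It deliberately
contains no physics engine: the synthetic generator is geometry plus noise,
so every quantity the analyses report has an exact planted counterpart.

Internal units are nm and ps everywhere; wavenumbers are nm⁻¹ with an
explicit Å⁻¹ conversion at the boundary (×10); masses are amu (default 1 for
synthetic protein atoms, atomic masses for ions); angles are degrees.

## Synthetic assemblies

`LatticeSpec` describes the lattice: `n_protofilaments`, an even number of
monomer layers (two per dimer), `sheet` or `cylinder` geometry, the axial
monomer spacing (default 4 nm, roughly a tubulin monomer), mid-wall radius
(default 10 nm) and per-protofilament helical rise (default 12/13 nm) for
cylinders. Monomers are conical-helix point clouds (chiral, non-collinear,
so superposition and centers of mass are non-degenerate); the first half of
each monomer's atoms are flagged backbone and every other backbone atom is a
Cα stand-in, giving each selection at least three non-collinear atoms per
dimer. Monomer labels alternate α/β along each protofilament with the dimer
axis α→β pointing toward the plus end (+z). Position classes mark the
outermost dimer layers (`plus_end`/`minus_end`, with the seam
protofilament's end dimers as `plus_corner`/`minus_corner` on cylinders) and
`central` elsewhere.

Planted dynamics: each dimer's coordinates are
`template + Σₖ aₖ(t)·modeₖ + noise` in the dimer's local frame, rotated into
its lattice placement (the placement transform is recovered exactly by a
Kabsch fit of the template onto the site). Amplitudes are i.i.d. Gaussian
per frame by default — covariance analysis is insensitive to frame order —
with an optional stationary Ornstein–Uhlenbeck correlation time for
time-sensitive observables. Planted directions are constructed from
wobble/twist/compression hinge patterns, then the template's six rigid-body
degrees of freedom are projected out before Gram–Schmidt orthonormalisation.
This is essential for exact recovery: the analysis superposes each subunit
onto a common reference, which annihilates precisely the rigid subspace, so
any rigid component planted into a mode would be silently removed and its
variance under-recovered. Given variance fractions fₖ of a total V, mode k
carries fₖ·V and the isotropic noise carries (1−Σf)·V spread over all 3M
coordinates, so recovered mode eigenvalues are fₖ·V + σ² with σ² the
per-coordinate noise variance — the small positive bias visible in recovered
fractions (≈+0.01 at the default settings) is this noise floor, not an
estimation error.

Bend plans impose protofilament curls: the dimers of a layer range are
rotated cumulatively (the c-th dimer by c·θ) about the lateral axis through
their intra-dimer interface, so every adjacent inter-dimer pair in the range
shows exactly θ. A uniform rotation of all dimers would leave relative
angles at zero; the cumulative convention makes both a plus-end-only tilt
and a body-wide curl recoverable as class means.

Brownian tracers are independent Gaussian random walks with per-axis step
variance 2·D·dt, stored unwrapped; their MSD, G_s and F_s have closed forms
(6Dt, the Gaussian propagator, exp(−q²Dt)) used as oracles. The spec
validates that the rms displacement over the run stays below a quarter of
the smallest box length.

What the generator does *not* emulate: excluded volume, inter-subunit
coupling, anharmonicity, solvent structure, or any free-energy surface.
Passing recovery tests therefore demonstrates that the analysis chain is
correct and unbiased under its own assumptions (linear modes + isotropic
noise), not that real trajectories satisfy those assumptions.

## Superposition and concatenation

Kabsch fits minimise weighted RMSD over proper rotations (reflections
excluded via the determinant correction); point sets whose second covariance
singular value vanishes (collinear) are rejected. A batched variant fits all
frames in one vectorised pass and is tested frame-by-frame against the
scalar implementation. Mass-weighting is available everywhere but off by
default (for Cα-like selections it is near-irrelevant).

Concatenation superposes every subunit frame onto a common reference and by
default refits onto the mean structure of a first pass (two-pass fit),
removing the bias of an arbitrary reference from the covariance; a
fixed-reference mode is available. Subunits must share an atom-ordering
signature (monomer label, atom name, backbone flag, in canonical
α-then-β-by-id order); mismatches are an error rather than a silent
misalignment. RMSD time series use the first frame of a run as reference by
default, configurable.

## Essential dynamics choices

* Covariance convention: population (divide by N), non-mass-weighted by
  default.
* Eigenvector signs are fixed by making the largest-magnitude component
  positive, so overlap matrices and projections are reproducible across
  runs and solvers.
* Projections are centered dot products (row − mean)·v in nm; the variance
  of projections onto mode i equals λᵢ identically, which is asserted in the
  tests.
* The scree kink is operationalised as the forward second difference of
  log-eigenvalues dᵢ = ln λᵢ − 2 ln λᵢ₊₁ + ln λᵢ₊₂: a kink at mode i means
  the spectrum drops sharply after mode i. Kinks are ranked by dᵢ;
  geometric spectra (constant log-ratio) correctly yield none. Eigenvalues
  below 10⁻¹⁴ of the largest are excluded before taking logs.
* Projection histograms use symmetric-about-zero bin edges spanning at
  least ±4σ per axis, widened to cover every sample so counts are conserved
  exactly; empty bins are NaN in the log₁₀ map, distinct from log₁₀(1)=0.
* Convergence curves draw *disjoint* random subunit subsets (so the two
  mode sets share no data) and report the first-mode |inner product| and
  RMSIP over replicates with their standard errors.

## Bending choices

Angles are unsigned magnitudes from the clamped arccos of the axis dot
product. The inter-dimer variant (adjacent dimers along a protofilament) is
the default; the intra-dimer variant compares the two monomer half-axes
(terminal-atom-group COM to terminal-atom-group COM) within one dimer.
Per-frame records are the default, with a per-pair time-averaged
aggregation flag. Note a numerical caveat asserted in the tests: exactly at
0° the arccos is infinitely sensitive, so rotation-invariance at the 10⁻⁹ °
level is verified on bent configurations, while straight-lattice angles are
checked against an absolute 10⁻⁶ ° bound.

## Scattering choices

The ISF uses the isotropic sinc kernel rather than explicit q-vector
sampling — exact for isotropic systems and matching the scalar-q convention
of neutron-scattering practice. Time origins run over every
`origin_stride`-th frame within the first half of the trajectory by
default. Global center-of-mass motion is retained unless `remove_com` is
set (relaxation to zero requires global motion). G_s is normalised so that
Σ G·4πr²Δr = 1 by construction; the sinc-quadrature transform of G_s is an
independent route to F_s and the two are cross-checked to 1% on Brownian
tracers. Density profiles wrap coordinates into the (constant) box along
the profiled axis so the integrated profile recovers each species' total
mass exactly.

## Pipeline

`pipeline.run` validates the whole config before computing anything, forks
one deterministic random stream per analysis from the single top-level seed
(adding an analysis never perturbs another's randomness), isolates
per-analysis failures, and writes every CSV with a JSON sidecar recording
analysis, parameters, seed and package version — enough to regenerate any
output.

## Problem sizes and defaults

The validation experiments use: the 3×3 sheet (9 dimers, 20 atoms per
monomer) at 5 000 frames with planted fractions 0.15/0.10/0.08 of a total
variance of 0.03 nm²; the 78-dimer microtubule at 400 frames per subunit
with three nearly degenerate planted modes (fractions 0.05/0.045/0.04 of
0.12 nm²) so that a single subunit trajectory genuinely under-determines
the first mode — the regime in which concatenation visibly improves the
overlap (≈0.58 at N=1 to ≈0.98 at N=39); imposed bends of 11° (plus end)
and 4° (body-wide), the two magnitudes the bending statistics must resolve;
and 10⁴ Brownian tracers with D = 10⁻³ nm²/ps probed at q = 12.6 nm⁻¹,
where q²Dt spans 0–3 within 64 frames. These sizes give statistical errors
comfortably below every tolerance asserted in the tests while keeping the
whole suite at laptop scale.

## Known limitations

* The generator's subunits are statistically identical; analyses of
  position-class differences (plus vs minus end) can be exercised but only
  show differences when a bend plan or class-specific dynamics is planted.
* Mass-weighted modes live in mass-weighted coordinates; no un-weighting
  transform is provided.
* The intra-dimer bending variant depends on the terminal-group split of
  the monomer atom list and is only meaningful for templates where that
  split is geometrically sensible.
* Binary MD trajectory formats are out of scope; adapters can wrap the
  `TrajectorySet` contract, and their wrapping conventions must be
  documented by the adapter (the scattering functions assume unwrapped
  coordinates).
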