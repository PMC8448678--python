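# assembly-ed

Essential dynamics, bending geometry and single-particle scattering
observables for trajectories of tubulin assemblies (protofilament sheets and
microtubule fragments), together with a synthetic trajectory generator that
plants known dynamics so every analysis stage can be validated by parameter
recovery — no molecular dynamics engine required.

## Who this is for

Simulators of microtubules and other filamentous protein assemblies who want
to extract the collective motions of the repeating subunit (the αβ-tubulin
heterodimer) from all-atom trajectories, and to know how well those motions
are determined by the available sampling.

## The core computations

**Concatenated-subunit essential dynamics.** A single heterodimer trajectory
rarely samples the subunit's configuration space ergodically. Instead, the
trajectories of all equivalent heterodimers in the assembly are
least-squares superposed (Kabsch) onto a common reference and pooled into
one long ensemble before principal component analysis. With rows
x ∈ ℝ^{3M}, the population covariance C = ⟨(x−⟨x⟩)(x−⟨x⟩)ᵀ⟩ is
eigendecomposed into orthonormal modes vᵢ with variances λᵢ (nm²). The scree
plot λᵢ vs i and its Cattell kink (the mode i where the forward second
difference of ln λ is largest and positive) separate the essential subspace
from the harmonic-noise floor. Mode similarity between systems or subsets is
quantified by inner-product matrices |vᵢ·uⱼ| and RMSIP
= √(k⁻¹ Σᵢⱼ (vᵢ·uⱼ)²); convergence with the number N of concatenated
subunit trajectories is measured as the first-mode overlap between disjoint
subsets of size N.

**Protofilament bending.** The bending angle between adjacent heterodimers
on one protofilament is the angle between the two monomer-COM → monomer-COM
axes, unsigned in [0°, 180°], summarised per lattice-position class
(plus end / minus end / body).

**Scattering observables.** The self van Hove function G_s(r,t) is the
displacement-magnitude distribution over particles and time origins; its
isotropic spatial Fourier transform is the self-intermediate scattering
function F_s(q,t) = ⟨sin(qΔr)/(qΔr)⟩ with F_s(q,0)=1, computed for scalar q
(nm⁻¹; 1.26 Å⁻¹ ≡ 12.6 nm⁻¹). Axis-resolved mass density profiles report
ion/protein distributions across the simulation box.

**Synthetic generator.** `build_lattice` constructs sheet or cylinder
lattices (e.g. the 3×3-heterodimer sheet or the 13-protofilament × 6-turn,
78-dimer microtubule fragment); `generate_trajectory` superimposes a few
orthonormal *planted* modes with prescribed variances, isotropic Gaussian
noise, and optional imposed protofilament bends; `generate_tracers` produces
free Brownian particles with exactly known G_s and F_s.

## Worked example

```sh
assembly-ed demo --outdir demo_run --seed 0
```

generates a miniature 3×3 sheet with planted mode fractions 0.15/0.10/0.08
and runs the full analysis graph. The report includes (seed 0):

```
"pca": {
 "first_three_fractions": [0.1832, 0.1197, 0.0991],
 "kink_mode": 3,
 "total_variance_nm2": 0.0274
}
```

i.e. the three planted modes are recovered as the top three principal
components and the scree kink falls at mode 3, the planted
essential-subspace boundary. The fractions sit ~0.02–0.03 above the planted
values because the demo system is deliberately tiny (48 coordinates, 300
frames): the isotropic noise floor adds its per-coordinate variance to each
mode's eigenvalue. At the production size used by the analysis drivers and
the acceptance script (20 atoms per monomer, 5 000 frames) the recovered
fractions are 0.161/0.108/0.089 — within ±0.011 of the planted
0.15/0.10/0.08.
The full-size numbered drivers live under `analysis/`
(`01_build_systems.py` … `07_scattering.py`); each prints what it found and
writes figure-ready CSVs under `results/`. For example
`analysis/05_convergence.py` reports the first-mode overlap between disjoint
subunit subsets rising from ≈0.58 for single trajectories to ≈0.98 at
N = 39 on the 78-subunit microtubule.

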