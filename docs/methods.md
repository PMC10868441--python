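# Methods

This note records the models implemented in ensemblekit, the conventions
chosen where several were defensible, and what the synthetic test data can
and cannot establish.

## Ensemble representation

An ensemble is a list of conformers of one polypeptide plus a normalized
weight vector. On disk this is a multi-model PDB file; conformer weights
live in a plain-text sidecar (one weight per model, `#` comments allowed)
because the PDB format has no weight field, and default to uniform 1/C.
Weights are renormalized on load to |Σw − 1| < 1e−12; negative or all-zero
weights are errors. Author residue numbering is preserved everywhere;
internal arrays are 0-based positional. Alternate locations other than
blank/'A' are dropped with a warning; heteroatoms and waters are excluded
unless explicitly requested; atomic masses and electron counts come from
the element tables of gemmi, and an unknown element is an error rather
than a silent zero.

Analyses consume two reductions: the Cα trace (C × N × 3) and the backbone
dihedrals φ_i = C(i−1)–N(i)–Cα(i)–C(i), ψ_i = N(i)–Cα(i)–C(i)–N(i+1)
(IUPAC sign convention). Dihedrals spanning a peptide bond longer than
2.5 Å (chain break) or missing a neighbor (termini) are NaN and excluded
per site with weight renormalization, rather than propagating missingness
to the whole residue.

## Conformer-space similarity

DRMSD is computed as the Euclidean distance between conformers' vectors
of internal Cα–Cα distances scaled by 1/sqrt(N(N−1)/2). This makes the
conformer-space embedding explicit: D is exactly a Euclidean metric, so
the weighted mean square cross distance decomposes as
Δ_kl = Δ_kk/2 + Δ_ll/2 + ‖μ_k − μ_l‖², where μ is the weighted mean
internal-distance vector. The test suite uses this decomposition as an
independent oracle for Δ and s. Conventions:

* Δ_kk includes the self-pairs (contributing zero), so Δ_kk = 0 exactly
  when all conformers of k are identical point sets.
* s_kl = sqrt(Δ_kk·Δ_ll)/Δ_kl; this is the only dimensionless reading
  that gives s = 1 for identical ensembles. The degenerate case
  Δ_kl = 0 (identical singletons) returns s = 1.
* The AM–GM inequality applied to the decomposition gives 0 ≤ s ≤ 1.
* Ensembles of unequal residue count are rejected; subsetting to a
  common range is an explicit user action.

The Shannon entropy of the weights uses the decadic logarithm, so uniform
weights over C conformers give log₁₀ C.

## Site-specific order and flexibility

The order parameter works on unit vectors between consecutive Cα atoms.
For each vector pair the weighted ensemble variance σ² of cos θ_ij is
converted to K_ij = 1 − √2·σ_ij, clipped to [0, 1]. The √2 factor is
fixed by the endpoints: σ² → 1/2 for a uniform θ distribution must give
K = 0, and σ = 0 must give K = 1. (Values below zero can occur for
bimodal cos θ with σ² > 1/2, hence the clip.) The site order
o_i = (1/N_v) Σ_j K_ij averages over all N_v = N−1 bond vectors including
j = i — vectors, not residues, are the objects of the statistic. For
mutually independent isotropic vectors var(cos θ) = 1/3, so distant pairs
tend to K ≈ 1 − √(2/3) ≈ 0.1835, which is why the random-coil baseline of
the mean order (≈ 0.19 for a 267-residue chain) sits slightly above that
floor: only near-diagonal pairs carry persistence-length correlations.

Flexibility uses the circular resultant R = |Σ w e^{iα}| of each
dihedral's ensemble distribution: f_i = 1 − R(φ_i)/2 − R(ψ_i)/2 runs from
0 (rigid) to 1 (uniform dihedrals). At chain termini where only one
dihedral exists, f is computed from the defined one alone.

Random-coil reference bands (mean ± 1.96 σ of o over sites and of f per
residue class) are regenerated from a seeded unrestrained generator
ensemble on demand rather than cached or hard-coded, because they depend
on the Ramachandran library in use; regeneration takes about a second at
the default C = 1000.

## Random-coil scaling of chain sections

Section statistics are ensemble root-mean-square quantities,
r_ee,i,j = sqrt(Σ w_c r²_ij,c), mirrored for section gyration radii
(Cα atoms, equal masses). The Flory fit minimizes the squared residual of
b₀·ΔN^ν against **all** sections in linear r space, unweighted,
initialized at b₀ = 3.8 Å, ν = 0.5, with ν constrained to [0.1, 1.0];
no per-ΔN weighting or log-space fitting is applied. The section
deviation matrix S_ij = r_ee,i,j − r̄_ee(j−i) is exactly centered within
each section length by construction — the test suite asserts this to
1e−9 — while P and C are relative deviations from the fitted law (C with
its own (b₀g, νg) fit to the gyration radii). Heat maps use a diverging
colormap, blue = compact, red = expanded.

## Domain partitioning and protein classes

The PAE algorithm operates on the symmetrized matrix (element-wise mean
with its transpose; entries above the 31.75 Å cap are clipped with a
warning). Steps, in order: binarize at t_domain; for each residue compute
the longest run e_i of consecutive low partners to its C-terminal side
(truncated at the chain end); smooth e with a centered width-5 moving
average whose window shrinks at the termini, rounding half away from
zero; then loop — seed a domain (i_max, i_max + e_max) at the largest
e (lowest index wins ties), refine by growing the interval outward while
the candidate residue's mean PAE to the current members is below
t_domain (contiguous growth only, which keeps domains intervals), zero e
over the domain and mask its rows/columns in M with 10⁶ — while
e_max ≥ 25. Domains separated by linkers shorter than 3 residues are
merged. The default t_domain = 10.58 Å is one third of the PAE cap.

Classification: D with no domains, Mf with two or more, otherwise Sf if
either terminal segment outside the single domain has ≥ 10 residues,
else F. The 1-D track variant marks residues ordered by a strict
threshold rule (eSpritz-style disorder scores: ordered when
score < 0.15; CheZOD-style order scores: ordered when ≥ 8), keeps
ordered runs of ≥ 25 residues and merges across < 3-residue gaps.
Threshold sweeps (e.g. 8.58–12.58 Å) report the class per threshold and
the fraction per class as a stability summary. The mean-PAE disorder
parameter averages entries with |i−j| ≥ 10, since PAE is small near the
diagonal even for IDPs.

## Shape, density and surface potential

The inertia tensor is mass-weighted and taken about the center of mass.
Eigenvalues are ordered I_x ≤ I_y ≤ I_z and the eigenvector matrix is
forced to determinant +1 (no reflections). If the first atom of the
N-terminal residue lands at larger x or z than the last atom of the
C-terminal residue, one of the three proper π-rotations about a principal
axis is applied — the one minimizing x_N + z_N, ties toward the rotation
about y — anchoring the chain direction without ever mirroring the
structure. Which two signs the convention flips is a package convention;
any fixed choice serves the purpose (consistent superposition).

The pseudo-density sums per-atom isotropic Gaussians (amplitude =
electron count; σ = 1.0 Å for heavy atoms, 0.7 Å for hydrogens) on a
regular grid (default 1 Å spacing, 5 Å padding), combining conformers
with their weights; voxel values integrate the kernel over the voxel so
the grid total approximates the ensemble's electron count (midpoint
quadrature is accurate to ≪ 1 % at these widths). The isolevel is the
largest τ whose super-level set contains the requested fraction (default
99.9 %) of the total. Maps are written as CCP4/MRC via gemmi.

Surface charges use Henderson–Hasselbalch fractions at the given pH with
standard solution pKa values (Asp 3.65, Glu 4.25, Lys 10.53, Arg 12.48,
His 6.08): carboxylates at the O-pair midpoint, Lys at NZ, Arg at the
NH1/NH2 midpoint, His at the ND1/NE2 midpoint, and phosphorylated
Ser/Thr/Tyr as −2 at the midpoint of the three terminal phosphate
oxygens. Terminal backbone charges are off by default. The potential at
each marching-cubes isosurface vertex is Σ q·exp(−d/λ_D)/d with
λ_D = 0.304/√(I[M]) nm (7.85 Å at the default 150 mM); the 1/d Coulomb
factor is the standard Debye–Hückel form. Per-conformer potentials are
averaged with the conformer weights. Residues with missing side-chain
atoms (e.g. backbone-only models) skip their charge with a warning — a
backbone-only ensemble therefore has identically zero surface potential.

## Chain generator

Backbones are grown with ideal geometry (N–Cα 1.458 Å, Cα–C 1.525 Å,
C–N 1.329 Å, C=O 1.231 Å; trans ω; standard bond angles) by natural
extension (NeRF), vectorized across conformers, from dihedrals drawn
from per-class Ramachandran basin mixtures:

| class   | basins (φ, ψ in °; weight)                                         |
|---------|--------------------------------------------------------------------|
| general | β/PPII (−110, 135; 0.65), α_R (−63, −43; 0.28), α_L (55, 45; 0.07) |
| Gly     | (−90, 150; 0.42), (90, −150; 0.14), (−70, −30; 0.30), (70, 30; 0.14) |
| Pro     | PPII (−65, 145; 0.78), α (−65, −30; 0.22)                          |
| Thr     | (−110, 140; 0.72), (−65, −40; 0.28)                                |

Basin widths are wrapped Gaussians of 10–25°. The layout encodes the
accepted qualitative features of coil-library statistics — near-mirror
symmetry for Gly, φ pinned near −65° for Pro, only the second/third
quadrants for Thr — with weights chosen once so the class-mean
flexibilities of an unrestrained ensemble fall in the documented
random-coil ranges (Gly ≈ 0.7 > other ≈ 0.44 > Thr ≈ 0.35 > Pro ≈ 0.23).
These are basin *mixtures*, not empirical coil-library densities, so
analyses against real coil libraries will differ in the second decimal.

Excluded volume is Cα-only: conformers with any pair |i−j| ≥ 3 closer
than 4.0 Å are rejected and resampled whole (whole-conformer restart is
unbiased; segment resampling is not attempted). Distance restraints use
von Neumann rejection against a target histogram: a conformer is kept
with probability min(1, p(r)/(p_max·a)) where a is the configured
acceptance fraction; a < 1 flattens the top of the target, trading
fidelity for acceptance rate. Sustained rejection beyond the configured
restart budget raises an error with the observed acceptance rate. All
sampling is driven by one seeded generator; a fixed seed reproduces
coordinates bitwise.

Synthetic PAE matrices plant square low-PAE blocks (4 Å) on a high
background (22 Å) with 1 Å Gaussian noise, a linear near-diagonal ramp
(half-width 10 residues) mimicking the short-range error suppression of
real PAE matrices, symmetrization and clipping to [0, 31.75 Å].

## What the synthetic data do and do not show

Generator ensembles emulate the *statistical* structure of disordered
chains: correct dihedral marginals per class, ≈ 3.8 Å Cα spacing, ν ≈ 0.5
without excluded volume and ν in (0.5, 0.65] with it, and flat order
profiles. They contain no side chains, no secondary-structure
propensity beyond the basin weights, no cis-proline, no chain
compaction from transient contacts, and uniform weights. Passing tests
therefore establish the correctness of the estimators and conventions,
not the realism of any particular ensemble; analyses of experimental
deposits (weighted, all-atom, restrained) exercise exactly the same code
paths through the same multi-model-PDB interface. Synthetic stand-ins
used where a database deposit would otherwise be required are labelled
`synthetic` in file names and docstrings.

## Problem sizes and numerical choices

Default problem sizes used by the test suite and the reproduction script
were chosen to make every statistic stable to well within its assertion
band: C = 1000 conformers for the 267-residue random-coil baseline
(mean order stable to ±0.0005 across seeds), C = 400–500 for scaling
fits, 50 seeded matrices for planted-domain recovery. Tolerances follow
the statistic: exact identities (S centering, decomposition, round
trips) are asserted at 1e−6–1e−12; sampled quantities at 2–3 σ of their
sampling noise. Degenerate inputs are defined rather than accidental:
single-conformer ensembles have Δ_kk = 0 and entropy 0; a 1-residue
chain has no dihedrals; an empty domain list is a valid partition
(class D); near-degenerate inertia spectra warn that the PAS orientation
is unstable.

## Known limitations

* Ensembles must share residue count for comparison; no alignment or
  common-range subsetting is done implicitly.
* The PAE refinement grows domains contiguously; genuinely discontiguous
  domains (e.g. inserted domains splitting another) are reported as
  separate intervals.
* The electrostatic surface model is semiquantitative by design: point
  charges, uniform dielectric, no Poisson–Boltzmann solve, no cation–π
  or hydrophobicity coloring.
* The generator builds backbones only (N, Cα, C, O); mass- and
  electron-weighted analyses of generated ensembles reflect backbone
  atoms alone.
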