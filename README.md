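# ensemblekit

Analysis and comparison of weighted conformer ensembles of intrinsically
disordered proteins (IDPs) and regions (IDRs).

Structured proteins are described well by a single set of coordinates;
disordered proteins are not. The working object here is a **weighted
conformer ensemble**: *C* atomistic conformers of one sequence with a
normalized weight vector *w* (multi-model PDB files, as deposited in
ensemble databases, plus an optional plain-text weight sidecar). The
package answers the questions practitioners of integrative ensemble
modeling ask of such objects:

* **How similar are two ensembles?** Conformers are points in an abstract
  Euclidean *conformer space* where the metric is the distance
  root-mean-square deviation of internal Cα–Cα distances,

      D(a,b) = sqrt( 2/(N(N−1)) · Σ_{i<j} (r_ij,a − r_ij,b)² ).

  The weighted mean square distance over all conformer pairs of two
  ensembles k, l is Δ_kl = Σ Σ w_k w_l D², and the single-valued
  similarity

      s_kl = sqrt(Δ_kk · Δ_ll) / Δ_kl

  is 1 for identical ensembles and 0 for two distinct single conformers,
  abstracting from ensemble width.

* **Where along the chain is there residual order?** A long-range order
  parameter o_i from the ensemble variance of cos θ between Cα–Cα bond
  vectors (K_ij = 1 − √2·σ_ij, o_i = mean_j K_ij), and a local
  flexibility parameter f_i = 1 − R(φ_i)/2 − R(ψ_i)/2 from the circular
  resultants of the backbone dihedrals. Both come with random-coil
  reference bands from an unrestrained generated ensemble.

* **Does the chain deviate from a Flory random coil?** Section
  end-to-end distances r_ee,i,j are fitted to r_ee = b₀·ΔN^ν (Kuhn
  length b₀, scaling exponent ν: 1/3 poor, 1/2 θ-, 0.588 good solvent),
  and per-section deviations are resolved in the proximity (P),
  compactness (C) and section-length-deviation (S) matrices.

* **Which parts are folded?** Folded domains are detected as low blocks
  of an AlphaFold predicted-aligned-error (PAE) matrix (threshold
  10.58 Å, minimum size 25 residues) or as ordered runs of a 1-D
  disorder track, and the protein is classified F / Sf / Mf / D (fully
  folded, single domain with terminal IDR, multiple domains, IDP).

* **What does the ensemble look like?** Conformers are superposed in the
  principal axes system of their inertia tensor, rendered as a
  pseudo-electron density with a 99.9 % isolevel, and colored by a
  Debye-screened electrostatic surface potential.

A seeded Monte-Carlo **chain generator** builds backbone ensembles from
residue-type-specific Ramachandran basin mixtures (with optional Cα
excluded volume and distance-restraint rejection sampling) and plants
synthetic PAE matrices, providing reproducible inputs for all analyses.

## Worked example

Generate two unrestrained 60-residue ensembles of the same low-complexity
sequence from different seeds, then compare and analyze them:

```sh
SEQ=$(python -c "from ensemblekit.generator import idr_like_sequence; \
print(idr_like_sequence(60, seed=1))")
ensemblekit generate -s "$SEQ" -n 40 --seed 11 -o genA
ensemblekit generate -s "$SEQ" -n 40 --seed 12 -o genB
ensemblekit similarity genA/ensemble.pdb genB/ensemble.pdb \
    -w genA/ensemble.weights -w genB/ensemble.weights -l A -l B -o simAB
ensemblekit coil genA/ensemble.pdb -o coilA
ensemblekit profile genA/ensemble.pdb --reference-conformers 200 -o profA
```

This prints

```
generated 40 conformers (seed 11); wrote genA
generated 40 conformers (seed 12); wrote genB
wrote similarity matrix for 2 ensembles to simAB
b0 = 5.258 A, nu = 0.5554; wrote coilA
mean order 0.2246; wrote profiles to profA
```

and `simAB/similarity.json` contains

```json
{"A|B": {"s": 0.9849889972884206,
         "delta_kk": 188.07308921527684,
         "delta_ll": 177.45553343684205,
         "delta_kl": 185.47130291789665,
         "entropy_k": 1.6020599913279623,
         "entropy_l": 1.6020599913279623}}
```

Two independent samples of the same random-coil distribution are almost
but not quite identical (s ≈ 0.985 — the residual deviation from 1 is
finite-sample noise at C = 40); each ensemble has conformer-space width
Δ_kk ≈ 180 Å² and Shannon entropy log₁₀ 40 ≈ 1.60 (uniform weights). The
coil fit ν ≈ 0.56 sits between the θ- and good-solvent exponents, and the
mean site order ≈ 0.22 is near the random-coil baseline for a chain of
this length. Domain partitioning works the same way
(`ensemblekit partition --pae pae.json --sweep 8.58 12.58 0.5 -o part`),
reporting the domain intervals, the F/Sf/Mf/D class and its stability
across the threshold sweep.

The same operations are available as library functions
(`ensemblekit.similarity_matrix`, `section_stats`, `partition_pae`,
`pas_ensemble`, `generate_ensemble`, ...); see `docs/methods.md` for the
models, conventions and parameter choices.

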