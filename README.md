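# msvtools

Mendelian sampling variances, trait-specific haplotype-similarity matrices,
and similarity-constrained optimal contribution selection for phased
genotypes.

## The problem

Genomic truncation selection picks parents on their breeding values alone
and, over generations, erodes the very haplotype diversity that future gain
depends on. Two quantities help manage that trade-off:

* the **Mendelian sampling variance (MSV)** of a parent — the variance
  among the breeding values of the gametes it can produce, driven by
  segregation at its heterozygous loci; and
* the **haplotype similarity** between two parents — how much of their
  Mendelian sampling potential comes from the *same* chromosome segments in
  the *same* linkage phase.

`msvtools` computes both analytically from phased biallelic genotypes, a
genetic map and additive marker effects, assembles the similarities into a
matrix usable as a quadratic constraint, and optimises parent contributions
against that constraint. A compact stochastic simulator compares selection
schemes built from these pieces.

## The model

For parent *i*, marker effects are given parent-specific signs
`m_ik = δ_ik · m_k`, where the phase indicator `δ_ik` is +1 if the reference
allele sits on the first haplotype, −1 on the second, and 0 at homozygous
loci. With the within-family LD matrix `R` (block-diagonal per chromosome,
`ρ_kl = exp(−2 d_kl)/4` under Haldane's map function, `d_kl` in Morgans):

* gamete MSV: `var(b_i) = Σ_c m_ic' R_c m_ic`
* gametic similarity: `s_ij = Σ_c |m_ic' R_c m_jc|`  (so `s_ii` is the MSV,
  and the value does not depend on the arbitrary haplotype storage order)
* zygote MSV of a mating: `var(b_ij) = var(b_i) + var(b_j)`; zygotic
  similarity matches sire-with-sire and dam-with-dam
* standardised similarity: `K = D⁻¹ S D⁻¹` with `D = diag(√MSV)`, giving a
  unit diagonal and off-diagonals in [0, 1]
* contribution optimisation: maximise `n'r` subject to `n'Qn/2 ≤ Q̄`,
  `n'v_f = n'v_m = 1/2`, `n ≥ 0`, where `Q` is `S`, `K`, or a VanRaden
  Method 1 GRM (the GRM case is classical OCS — same solver, different
  matrix)
* selection index: `I = b + 2·x_p·σ_g` with `x_p` the standard-normal
  truncation point for selected proportion *p* and `σ_g = √MSV`

`R` is built once per chromosome and shared across all parents and traits;
the one-off matrix plus cheap signed-effect vectors is what makes the MSV
and the full similarity matrix affordable at tens of thousands of markers.
An exhaustive segregation-pattern enumerator (exact up to 20 loci) serves
as the ground-truth oracle for all of the above.

## Worked example

Two parents, three markers, adjacent recombination fractions 0.1 and 0.2,
effects (1, 0.2, 0.02). Parent 1 carries the reference allele on its whole
first haplotype; parent 2 on loci 1 and 3.

```python
import numpy as np
import msvtools as mt

gmap = mt.GeneticMap.from_recombination_fractions([0.1, 0.2])
hap = np.array([[[1, 1, 1], [0, 0, 0]],
                [[1, 0, 1], [0, 1, 0]]], dtype=np.int8)
geno = mt.PhasedGenotypes(hap, np.array(["p1", "p2"]))
eff = mt.MarkerEffects([[1.0, 0.2, 0.02]], ("trait",))

R = mt.build_R_all(gmap)
m1 = mt.signed_effects(geno, gmap, eff, "p1")
m2 = mt.signed_effects(geno, gmap, eff, "p2")
print(round(mt.gamete_msv(m1, R), 4))              # 0.3461
print(round(mt.gamete_msv(m2, R), 4))              # 0.1837
print(round(mt.pairwise_similarity(m1, m2, R), 4))  # 0.2449
K = mt.standardize(mt.build_S(geno, gmap, eff))
print(round(K.values[0, 1], 4))                    # 0.9713
```

The two MSVs say parent 1's gametes vary almost twice as much as parent
2's; the similarity 0.2449 is close to its Cauchy–Schwarz ceiling
(`0.2449/√(0.3461·0.1837) ≈ 0.97`), i.e. these parents owe their Mendelian
sampling potential to essentially the same heterozygous segments — mating
both heavily would concentrate, not diversify, the next generation's
haplotypes.

The same numbers come out of the exhaustive oracle and the CLI:

```bash
msvtools fixtures demo/
msvtools msv --haplotypes demo/haplotypes.tsv --map demo/markers.map \
             --effects demo/effects.tsv
msvtools oracle --theta 0.1,0.2 --effects 1,0.2,0.02 \
                --haplotypes '111/000,101/010'
```

Other subcommands: `similarity` (S/K matrices, optional nearest-PSD
repair), `mocs` (contribution optimisation), `simulate` (the scheme
simulator).

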