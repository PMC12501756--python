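# Methods

## Model and assumptions

All computations assume **phased, complete, biallelic** genotypes, a
genetic map in Morgans, and known (or externally estimated) additive marker
effects. Inheritance follows Haldane's model: no crossover interference, so
the recombination fraction between two markers at map distance *d* is
`θ = (1 − e^{−2d})/2`, and markers on different chromosomes segregate
independently. Dominance, epistasis, mutation and genotyping error are out
of scope.

The allele labelled "reference" is the one coded 1 in a haplotype; the
genotype indicator is `c = h1 + h2 − 1 ∈ {1, 0, −1}` and the phase
indicator `δ = h1 − h2 ∈ {1, 0, −1}`. VCF input maps REF (GT code 0) to
the internal reference allele. Breeding values are `b = c'm`.

### Mendelian sampling variance

The covariance between the transmitted-allele indicators of two markers in
a heterozygous parent is `±e^{−2d}/4`, the sign set by the linkage phase.
Two equivalent formulations follow:

* the *legacy* route builds a **parent-specific** matrix `R_i` with those
  signs baked in and homozygous rows/columns zeroed, and computes
  `m' R_i m` with the population effect vector — an O(p²) matrix per
  parent (kept in `msvtools.validation` as a cross-check);
* the *shared-matrix* route moves the phase signs into the effect vector
  (`m_ik = δ_ik m_k`) so that a single all-positive `R` per chromosome
  serves every parent and trait: `var(b_i) = Σ_c m_ic' R_c m_ic`.

The package's tests assert the algebraic identity of the two routes to
1e−10 on hundreds of random instances, and both against exhaustive
segregation-pattern enumeration.

### Similarity and its absolute-value convention

The bilinear form `m_ic' R_c m_jc` changes sign when either parent's
haplotypes are swapped — an arbitrary storage choice. The absolute value
is therefore taken **per chromosome** before summing, for the gametic,
aggregate-genotype and zygotic forms alike (for zygotes, per parental term
per chromosome). This guarantees invariance to haplotype order, makes a
monozygotic twin pair standardise to exactly +1, and keeps `s_ii` equal to
the MSV. The per-chromosome (rather than grand-total) placement of the
absolute value is a genuine convention choice; we use the per-term reading
consistently and test the invariance exhaustively over all flip
combinations on small instances.

### Standardisation

`K = D⁻¹ S D⁻¹` where `D` is the **diagonal of Mendelian standard
deviations**, `D_ii = √S_ii`. Entities with MSV below 1e−12 (fully
homozygous at every effect locus) carry no Mendelian sampling information
and are excluded from `K` with a logged warning rather than producing a
division by zero. Off-diagonals obey `0 ≤ k_ij ≤ 1` by Cauchy–Schwarz
applied per chromosome plus the triangle inequality over chromosomes.

### Indefiniteness and nearest-PSD repair

`S` is a sum of per-chromosome *absolute values* of Gram-like forms, so it
need not be positive semidefinite — especially when parents outnumber
informative (heterozygous, non-zero-effect) markers. `near_pd` applies
Higham-style alternating projection onto the PSD cone, which without
additional constraint sets reduces to eigenvalue clipping, iterated until
the smallest eigenvalue is within tolerance (default 1e−8 relative, 100
iterations). It is idempotent on PSD input and is applied to any
constraint matrix before optimisation.

## Segregation oracle

For ≤ 20 loci on one chromosome, all `2^L` gamete segregation patterns are
enumerated with probabilities `½·Π(θ or 1−θ)` over adjacent intervals
(log-space products against underflow). Variances and matched-pattern
covariances from this distribution are exact, which makes the oracle the
ground truth for every matrix expression. Two subtleties:

* the covariance between two parents' gametes is taken over the
  **matched-pattern (conditional) distribution** — the same pattern in
  both parents — because the joint distribution of two independent
  meioses has covariance identically zero;
* the zygote MSV *is* computed from the joint distribution of two
  independent parental draws, since a zygote combines two independent
  gametes.

The pattern-swap symmetry (A↔B) negates heterozygous contributions only;
parents with homozygous effect loci have a non-zero mean gamete value
(a constant offset that cancels from every variance and covariance). The
zero-mean property therefore holds for fully heterozygous parents, which
is how the tests state it.

## Contribution optimisation

The program is: maximise `n'r` subject to `n'Qn/2 ≤ Q̄`, per-sex sums
`n'v_f = n'v_m = 1/2`, `0 ≤ n ≤ u`. With `Q` PSD this is convex. The
solver stack, in order:

1. **Whole-sex elimination.** A sex whose bounds leave no slack (upper
   bounds summing exactly to its half — e.g. truncation-selected females
   pinned at uniform contributions) is eliminated analytically; its block
   folds into a linear term of the quadratic constraint.
2. **Active-set core.** If the cap is slack at the linear-program optimum
   (greedy fill of the best candidates up to their caps), that optimum is
   returned. Otherwise the cap is an equality and, for a working set of
   free coordinates, stationarity is solved in closed form
   (`x_S(t) = t·v1 + v2`, `t = 1/μ` fixed by the cap as the root of a
   scalar quadratic); bound violators are clamped and wrongly-signed
   reduced costs released one at a time.
3. **Fallbacks.** SLSQP (with a restart and an exact feasibility
   restoration along the segment to a strictly feasible point when its
   line search stalls), then a trust-region solve.

Every candidate solution is **verified** — sums to 1e−8, cap to 1e−8,
bounds — and certified by an explicit KKT check (multipliers estimated by
least squares on free coordinates; sexes with no free coordinate get their
multiplier from interval feasibility) before being reported optimal. An
infeasible cap yields an explicit `infeasible` status, never a silent
relaxation.

Cardinality (min/max sire counts) cannot be expressed in the continuous
program. The max-sire rule iteratively zeroes the upper bounds of the
weakest supported males and re-solves (≤ 50 rounds); the min-sire rule
gives the best unsupported males a small floor `1/(2N)` and re-solves with
lower bounds.

Constraint calibration scales the base-generation `S` by its maximum
element (or maximum MSV, switchable) and takes the requested percentile of
the scaled off-diagonal distribution as `Q̄`, reused unchanged in every
later generation. For `K` the matrix is already on a fixed [0, 1] scale,
so the cap is the percentile of the base `K` off-diagonals directly. For
GRM-based OCS the cap follows the standard per-generation recursion
`Q̄ = C̄ + ΔF·(1 − C̄)` with `C̄` the mean of `G/2` — the recursion itself
is an assumption, as only the target rates (1%, 0.5%) are standard.

Mating allocation converts male contributions to integer mating counts by
largest-remainder rounding of `n_i · 2F` (`F` females, totals preserved
exactly), enforces the per-male cap by redistributing the excess to the
next-best males, tops up to the minimum sire count one mating at a time,
and assigns males to females by a seeded shuffle.

## Breeding-program simulator

The simulator emulates a closed nucleus population with discrete
generations, balanced sexes, truncation-selected females (top 50%, one
mating each, 4 offspring per mating, offspring sexes alternating) and
males selected by truncation or by contribution optimisation.

* **Founders.** Marker allele frequencies are drawn from Beta(0.5, 0.5)
  (U-shaped, mimicking a drifted population), haplotypes sampled
  independently per marker, followed by 10 generations of random-mating
  burn-in so that within-chromosome LD is consistent with the map. This
  replaces a coalescent demography: absolute LD levels, heterozygosity
  (≈ 0.23 at the start, hence a high nominal `F = 1 − Ho`) and allele
  frequency spectra differ from a real cattle population, so only
  *relative* scheme comparisons carry over — a limitation the tests
  respect by asserting rankings, never magnitudes.
* **Meiosis.** The parental source of the transmitted allele follows the
  exact marker-skeleton Markov chain of Haldane's model: Bernoulli(1/2)
  start per chromosome, independent switches between adjacent markers
  with probability `θ_k`. With no interference this is the same law as
  sampling Poisson crossover positions on the continuum, and it
  vectorises over gametes (the simulation-versus-formula test draws
  100k gametes in one call).
* **Selection.** True QTL effects serve as "known marker effects", so
  breeding values and MSVs are exact — the known-effects assumption.
  Similarity matrices are computed on QTL markers (a switch for SNP-based
  matrices exists but requires estimated SNP effects, which are out of
  scope). The contribution problem is posed over both sexes with the
  selected females pinned at uniform contributions, so the quadratic cap
  sees male, female and cross blocks. The per-male mating cap (a fifth of
  all matings, the full design's 50-of-250 rule scaled proportionally) is
  imposed as the male contribution upper bound.
* **Monitoring.** Per generation: gain in base-generation genetic-SD
  units, SD of true breeding values, `F = 1 − Ho` over SNPs, favourable
  QTL alleles lost (favourable = the allele whose substitution effect is
  positive; lost = frequency exactly zero), mean favourable allele
  frequency, SNP alleles fixed, and the number of distinct sires used.

**Problem sizes.** The default configuration is 200 individuals,
3 chromosomes of 1 Morgan with 100 SNPs + 20 QTLs each, heritability 0.25,
QTL effects Normal(0, 100), 15 generations; the scheme-comparison test
runs 30 replicates per scheme. `SimConfig.paper_scale()` exposes the full
design (1000 individuals, 10 chromosomes, 1000 SNPs + 200 QTLs each,
50 generations), which is intended for cluster use. At the default scale
the scheme contrasts are directional: tightly constrained
similarity-based selection ends with more genetic SD and fewer favourable
QTL alleles lost than truncation on breeding value, and tighter caps
spread matings over more sires; the margins are modest because 15
generations and 100 male candidates leave selection and drift less room
to diverge than the full design does.

## Numerical choices

* Map input in cM is divided by 100 on read; all internal distances are
  Morgans. Recombination-fraction input is converted to cumulative
  positions through Haldane's function (`d = −0.5·ln(1 − 2θ)`).
* Co-located markers (map distance 0) are allowed with `ρ = 0.25`
  off-diagonal and a logged warning; real chips contain them.
* Missing, unphased or multi-allelic genotype records are rejected at
  read time with the offending marker and sample named — the method
  requires complete phased data.
* Mendelian covariance matrices are reported with tiny negative
  diagonal values (|v| < 1e−10, floating-point artefacts) clamped to zero
  in the `msv` accessor; stored matrices are never silently altered.
* Truncation-selection ties are broken by (criterion, candidate index)
  so runs are reproducible; all stochastic draws flow from an explicitly
  passed generator, one independent stream per replicate spawned from the
  master seed.
* An infeasible contribution problem mid-simulation falls back to the
  previous generation's contributions when configured
  (`infeasible_fallback`, default on), else aborts the replicate.

## Known limitations

* Haldane's map function only; no interference-aware alternatives.
* Gametic/zygotic similarity for dioecious species matches sire-with-sire
  and dam-with-dam; monoecious conventions are not implemented.
* Dense matrices throughout; populations beyond ~20k entities are outside
  the intended contract (the optimisation problems of interest are ≤ 1000
  candidates).
* The simulator's founders are not coalescent-realistic (see above), it
  simulates a single trait, and marker-effect estimation is out of scope
  — effects are inputs everywhere.
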