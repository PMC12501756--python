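"""Stochastic breeding-program simulator.

A compact, self-contained simulator for comparing truncation selection (TS)
against contribution optimisation under similarity (MOCS) or coancestry
(OCS) constraints.  The genome carries neutral SNPs and effect-bearing QTLs
on a shared genetic map; meiosis follows Haldane's model (no interference);
selection uses true QTL effects as if they were known marker effects, so
the analytical Mendelian-sampling machinery applies exactly.

Founder haplotypes are drawn marker-wise from U-shaped Beta(0.5, 0.5) allele
frequencies and mixed by a configurable number of random-mating burn-in
generations to establish map-consistent linkage disequilibrium.  This is a
deliberately simple substitute for a coalescent cattle demography: absolute
outcomes are not comparable with a real livestock population, but the
*relative* behaviour of selection schemes on gain, variance and allele
retention is.

Schemes (selection of males; females are always truncation-selected):

* ``TS-BV`` / ``TS-Index`` — truncation on breeding value or on the
  usefulness-style index.
* ``MOCS-S`` / ``MOCS-K`` — contribution optimisation under a cap on raw or
  standardised haplotype similarity, calibrated once from the base
  population.
* ``OCS-GRM`` — contribution optimisation under a mean-coancestry cap from a
  target inbreeding rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import mocs as mocs_mod
from .genome_model import (
    GeneticMap,
    MarkerEffects,
    PhasedGenotypes,
    build_R_all,
    inverse_haldane,
)
from .similarity import SimilarityMatrix, build_S, near_pd, standardize

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "PopulationState",
    "MonitorRecord",
    "make_base_population",
    "meiosis",
    "run_scheme",
    "monitor",
    "SCHEMES",
]

SCHEMES = ("TS-BV", "TS-Index", "MOCS-S", "MOCS-K", "OCS-GRM")


@dataclass(frozen=True)
class SimConfig:
    """Simulation design parameters.

    Defaults are a desk-scale design (minutes on one CPU): 200 individuals,
    3 chromosomes of 1 Morgan, 100 SNPs + 20 QTLs per chromosome,
    15 generations.  ``paper_scale()`` returns the full design (1000
    individuals, 10 chromosomes, 1000 SNPs + 200 QTLs each, 50 generations),
    which needs cluster-scale compute for many replicates.
    """

    n_individuals: int = 200
    n_chromosomes: int = 3
    chrom_length: float = 1.0  # Morgans
    snps_per_chrom: int = 100
    qtls_per_chrom: int = 20
    qtl_effect_var: float = 100.0
    heritability: float = 0.25
    n_generations: int = 15
    scheme: str = "TS-BV"
    constraint_percentile: float = 50.0  # MOCS: base-pop similarity quantile
    delta_f: float = 0.01  # OCS: target inbreeding rate per generation
    n_sires_ts: int = 5  # males under truncation selection
    female_proportion: float = 0.5
    offspring_per_mating: int = 4
    # cap on matings per male; None scales the full design's rule (at most
    # 50 of 250 females, a fifth of all matings) to the population at hand
    max_females_per_male: int | None = None
    min_sires: int = 5
    max_sires: int | None = None
    burn_in: int = 10
    founder_beta: tuple = (0.5, 0.5)
    similarity_markers: str = "qtl"  # 'qtl' (known effects) or 'snp'
    scale_mode: str = "max"
    index_criterion: bool = False  # MOCS/OCS criterion: index instead of BV
    index_proportion: float = 0.01  # p for the usefulness index
    infeasible_fallback: bool = True

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if not 0 < self.heritability <= 1:
            raise ValueError("heritability must lie in (0, 1]")
        for name in ("n_individuals", "n_chromosomes", "snps_per_chrom",
                     "qtls_per_chrom", "n_generations",
                     "offspring_per_mating"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_individuals % 2:
            raise ValueError("population size must be even (balanced sexes)")

    @classmethod
    def paper_scale(cls, **overrides) -> "SimConfig":
        """The full-scale design; cluster-scale for many replicates."""
        base = dict(
            n_individuals=1000, n_chromosomes=10, snps_per_chrom=1000,
            qtls_per_chrom=200, n_generations=50,
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class PopulationState:
    """One generation of the simulated population."""

    genotypes: PhasedGenotypes  # SNPs + QTLs interleaved on the map
    gmap: GeneticMap
    qtl_mask: np.ndarray  # True at QTL positions
    qtl_effects: np.ndarray  # per QTL marker, reference-allele effect
    generation: int = 0

    @property
    def true_bv(self) -> np.ndarray:
        """True breeding values: sum of QTL allele effects (c' m over
        QTLs)."""
        c = self.genotypes.genotype_indicator[:, self.qtl_mask].astype(float)
        return c @ self.qtl_effects

    @property
    def sex(self) -> np.ndarray:
        return self.genotypes.sex


@dataclass(frozen=True)
class MonitorRecord:
    """Per-generation monitored parameters."""

    generation: int
    gain: float  # mean BV increase over base, in base genetic-SD units
    genetic_sd: float  # SD of true BVs this generation
    inbreeding: float  # F = 1 - mean observed SNP heterozygosity
    qtl_alleles_lost: int  # favourable QTL alleles at frequency 0
    mean_favourable_freq: float
    snp_alleles_lost: int  # SNP loci fixed for either allele
    n_sires: int  # distinct sires used this generation

    def as_dict(self) -> dict:
        return {
            "generation": self.generation,
            "gain": self.gain,
            "genetic_sd": self.genetic_sd,
            "inbreeding": self.inbreeding,
            "qtl_alleles_lost": self.qtl_alleles_lost,
            "mean_favourable_freq": self.mean_favourable_freq,
            "snp_alleles_lost": self.snp_alleles_lost,
            "n_sires": self.n_sires,
        }


def _build_map(config: SimConfig) -> tuple[GeneticMap, np.ndarray]:
    """Evenly spaced SNPs and QTLs interleaved on each chromosome."""
    chroms, pos, ids, qtl_mask = [], [], [], []
    per = config.snps_per_chrom + config.qtls_per_chrom
    for c in range(config.n_chromosomes):
        # evenly spaced loci; every (snp+qtl)/qtl-th locus is a QTL
        p = np.linspace(0.0, config.chrom_length, per, endpoint=False)
        is_qtl = np.zeros(per, dtype=bool)
        step = per / config.qtls_per_chrom
        is_qtl[(np.arange(config.qtls_per_chrom) * step).astype(int)] = True
        chroms.extend([str(c + 1)] * per)
        pos.extend(p)
        ids.extend(
            f"c{c + 1}_{'q' if q else 's'}{k}" for k, q in enumerate(is_qtl)
        )
        qtl_mask.extend(is_qtl)
    gmap = GeneticMap(np.array(chroms), np.array(pos), np.array(ids))
    return gmap, np.array(qtl_mask)


def meiosis(haplotypes: np.ndarray, gmap: GeneticMap, rng,
            n_gametes: int = 1) -> np.ndarray:
    """Sample gametes from one phased parent under Haldane's model.

    ``haplotypes`` is (2, markers).  Along each chromosome the parental
    source of the transmitted allele follows a two-state Markov chain:
    Bernoulli(1/2) start, switching between adjacent markers with
    probability ``theta = (1 - exp(-2 d)) / 2``.  With no crossover
    interference this marker-skeleton chain is exactly the law induced by
    Poisson-process crossovers, and it vectorises over gametes.

    Returns an (n_gametes, markers) array of transmitted alleles.
    """
    n_markers = haplotypes.shape[1]
    source = np.empty((n_gametes, n_markers), dtype=np.int8)
    for c in gmap.chromosomes:
        idx = gmap.markers_on(c)
        theta = inverse_haldane(np.diff(gmap.position[idx]))
        start = rng.random(n_gametes) < 0.5
        switches = rng.random((n_gametes, len(idx) - 1)) < theta[None, :]
        src = np.empty((n_gametes, len(idx)), dtype=np.int8)
        src[:, 0] = start
        if len(idx) > 1:
            src[:, 1:] = switches
            np.bitwise_xor.accumulate(src, axis=1, out=src)
        source[:, idx] = src
    return np.where(source == 0, haplotypes[0][None, :],
                    haplotypes[1][None, :]).astype(np.int8)


def _mate(genotypes: PhasedGenotypes, gmap: GeneticMap, matings, rng
          ) -> np.ndarray:
    """Produce offspring haplotypes for a list of (sire_idx, dam_idx,
    n_offspring) tuples.  Returns (n_offspring_total, 2, markers)."""
    out = []
    for sire, dam, k in matings:
        pat = meiosis(genotypes.haplotypes[sire], gmap, rng, k)
        mat = meiosis(genotypes.haplotypes[dam], gmap, rng, k)
        out.append(np.stack([pat, mat], axis=1))
    return np.concatenate(out, axis=0)


def make_base_population(config: SimConfig, seed) -> PopulationState:
    """Founder population with burn-in LD.

    Marker allele frequencies are drawn from Beta(a, b) (default (0.5, 0.5),
    U-shaped, mimicking a drifted population), haplotypes sampled
    independently per marker, then ``config.burn_in`` generations of random
    mating build up map-consistent within-chromosome LD.  QTL effects are
    Normal(0, qtl_effect_var).  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    gmap, qtl_mask = _build_map(config)
    n, p_markers = config.n_individuals, gmap.n_markers
    freq = rng.beta(*config.founder_beta, size=p_markers)
    haps = (rng.random((n, 2, p_markers)) < freq[None, None, :]).astype(
        np.int8
    )
    sex = np.array(["M", "F"] * (n // 2))
    ids = np.array([f"G0_{k}" for k in range(n)])
    genotypes = PhasedGenotypes(haps, ids, sex)

    for g in range(config.burn_in):
        males = np.flatnonzero(genotypes.sex == "M")
        females = np.flatnonzero(genotypes.sex == "F")
        sires = rng.choice(males, size=len(females), replace=True)
        per = max(1, n // len(females))
        matings = [(s, d, per) for s, d in zip(sires, females)]
        haps = _mate(genotypes, gmap, matings, rng)[:n]
        genotypes = PhasedGenotypes(haps, ids, sex)

    qtl_effects = rng.normal(0.0, np.sqrt(config.qtl_effect_var),
                             size=int(qtl_mask.sum()))
    return PopulationState(genotypes, gmap, qtl_mask, qtl_effects, 0)


def monitor(state: PopulationState, base_mean: float, base_sd: float,
            n_sires: int) -> MonitorRecord:
    """Compute all monitored parameters for one generation."""
    bv = state.true_bv
    geno = state.genotypes
    snp = ~state.qtl_mask
    het = (geno.genotype_indicator[:, snp] == 0).mean()
    freq_ref = geno.dosage.mean(axis=0) / 2.0
    # favourable allele: the one whose substitution increases the trait
    qtl_freq_ref = freq_ref[state.qtl_mask]
    fav_freq = np.where(state.qtl_effects > 0, qtl_freq_ref,
                        1.0 - qtl_freq_ref)
    snp_freq = freq_ref[snp]
    return MonitorRecord(
        generation=state.generation,
        gain=float((bv.mean() - base_mean) / base_sd),
        genetic_sd=float(bv.std()),
        inbreeding=float(1.0 - het),
        qtl_alleles_lost=int(np.sum(fav_freq == 0.0)),
        mean_favourable_freq=float(fav_freq.mean()),
        snp_alleles_lost=int(np.sum((snp_freq == 0.0) | (snp_freq == 1.0))),
        n_sires=n_sires,
    )


def _criterion(state: PopulationState, config: SimConfig, R: dict,
               effects: MarkerEffects) -> np.ndarray:
    """Per-individual selection criterion (BV, or usefulness index)."""
    bv = state.true_bv
    if config.scheme == "TS-Index" or (
        config.scheme in ("MOCS-S", "MOCS-K", "OCS-GRM")
        and config.index_criterion
    ):
        from .msv import gamete_msv
        from .genome_model import signed_effects

        msvs = np.array([
            gamete_msv(
                signed_effects(state.genotypes, state.gmap, effects, pid), R
            )
            for pid in state.genotypes.sample_id
        ])
        return mocs_mod.selection_index(bv, msvs, config.index_proportion)
    return bv


def _select_females(bv_like: np.ndarray, sex: np.ndarray,
                    proportion: float) -> np.ndarray:
    females = np.flatnonzero(sex == "F")
    k = max(1, int(round(proportion * len(females))))
    # ties broken by (criterion, index) for determinism
    order = females[np.lexsort((females, -bv_like[females]))]
    return order[:k]


def _effects_for_similarity(state: PopulationState, config: SimConfig
                            ) -> MarkerEffects:
    """Marker effects used for MSV/similarity: true QTL effects (known-
    effects assumption), or SNP-only zeros when configured to study the
    estimated-effects gap."""
    m = np.zeros(state.gmap.n_markers)
    mask = state.qtl_mask if config.similarity_markers == "qtl" else None
    if mask is None:
        raise NotImplementedError(
            "similarity on SNPs requires estimated SNP effects; "
            "only 'qtl' is supported in simulation"
        )
    m[mask] = state.qtl_effects
    return MarkerEffects(m[None, :], ("trait",))


def run_scheme(config: SimConfig, seed, n_replicates: int = 1,
               base_population: PopulationState | None = None) -> list:
    """Run a selection scheme; returns a flat list of per-generation
    MonitorRecord dicts with a 'replicate' key.

    The quadratic constraint (MOCS) or coancestry cap (OCS) is calibrated
    once from each replicate's base population and held fixed thereafter.
    A master seed spawns one independent stream per replicate.
    """
    master = np.random.SeedSequence(seed)
    records = []
    for rep, child in enumerate(master.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        state = (base_population if base_population is not None
                 else make_base_population(config,
                                           child.spawn(1)[0]))
        records.extend(
            {"replicate": rep, **r.as_dict()}
            for r in _run_single(config, state, rng)
        )
    return records


def _run_single(config: SimConfig, state: PopulationState, rng
                ) -> list[MonitorRecord]:
    R = build_R_all(state.gmap)
    effects = _effects_for_similarity(state, config)
    base_bv = state.true_bv
    base_mean, base_sd = float(base_bv.mean()), float(base_bv.std())
    if base_sd == 0:
        raise ValueError("base population has zero genetic variance")

    # one-off constraint calibration from the base population
    scale = q_bar = None
    if config.scheme == "MOCS-S":
        S0 = _similarity_matrix(state, config, R, effects)
        _, q_bar, scale = mocs_mod.calibrate_constraint(
            S0, config.constraint_percentile, config.scale_mode
        )
    elif config.scheme == "MOCS-K":
        # K is already on a fixed [0, 1] scale; the cap is the requested
        # quantile of the base population's standardised similarities
        S0 = _similarity_matrix(state, config, R, effects)
        K0 = standardize(S0)
        q_bar = float(np.percentile(K0.off_diagonal(),
                                    config.constraint_percentile))

    records = [monitor(state, base_mean, base_sd, n_sires=0)]
    prev_solution = None
    for g in range(1, config.n_generations + 1):
        state, n_sires, prev_solution = _advance(
            config, state, R, effects, rng, q_bar, scale, prev_solution
        )
        records.append(monitor(state, base_mean, base_sd, n_sires))
    return records


def _similarity_matrix(state: PopulationState, config: SimConfig, R: dict,
                       effects: MarkerEffects,
                       males_only: bool = False) -> SimilarityMatrix:
    ids = state.genotypes.sample_id
    if males_only:
        ids = ids[state.sex == "M"]
    return build_S(state.genotypes, state.gmap, effects, mode="gametic",
                   trait=0, parents=ids, R=R)


def _advance(config, state, R, effects, rng, q_bar, scale, prev_solution):
    """One generation of selection, mating and reproduction."""
    crit = _criterion(state, config, R, effects)
    sex = state.sex
    females = _select_females(crit, sex, config.female_proportion)
    males = np.flatnonzero(sex == "M")

    if config.scheme in ("TS-BV", "TS-Index"):
        order = males[np.lexsort((males, -crit[males]))]
        sires = order[: config.n_sires_ts]
        counts = mocs_mod._largest_remainder(
            np.ones(len(sires)), len(females)
        )
        pairs = list(zip(np.repeat(sires, counts), females))
        n_sires = len(sires)
        solution = prev_solution
    else:
        cap = (config.max_females_per_male
               if config.max_females_per_male is not None
               else max(1, round(len(females) / 5)))
        male_contrib = _optimise(config, state, R, effects, crit, males,
                                 females, q_bar, scale, cap)
        if male_contrib is None:
            if config.infeasible_fallback and prev_solution is not None:
                logger.warning("generation %d infeasible; reusing previous "
                               "contributions", state.generation + 1)
                male_contrib = prev_solution
            else:
                raise RuntimeError(
                    f"contribution optimisation infeasible at generation "
                    f"{state.generation + 1}"
                )
        solution = male_contrib
        mating_list = mocs_mod.allocate_matings(
            male_contrib, list(males), list(females), rng,
            max_per_male=cap,
            min_males=config.min_sires,
        )
        pairs = mating_list
        n_sires = len({s for s, _ in pairs})

    matings = [(int(s), int(d), config.offspring_per_mating)
               for s, d in pairs]
    haps = _mate(state.genotypes, state.gmap, matings, rng)
    n = config.n_individuals
    haps = haps[:n]
    gen = state.generation + 1
    ids = np.array([f"G{gen}_{k}" for k in range(len(haps))])
    offspring_sex = np.array(["M", "F"] * (len(haps) // 2 + 1))[: len(haps)]
    genotypes = PhasedGenotypes(haps, ids, offspring_sex)
    return (
        replace(state, genotypes=genotypes, generation=gen),
        n_sires,
        solution,
    )


def _optimise(config, state, R, effects, crit, males, females, q_bar,
              scale, max_per_male):
    """Build and solve the per-generation contribution problem.

    The problem is posed over males *and* the truncation-selected females
    together, as in the full two-sex formulation: each selected female's
    contribution is pinned to the uniform 1/(2k) by equal lower/upper
    bounds (one mating each), unselected females are capped at zero, and
    only the male contributions are genuinely free.  The quadratic
    constraint therefore sees the male block, the male-female cross terms
    and the female block.  Returns the male contribution vector, or None if
    infeasible.
    """
    n = state.genotypes.n_individuals
    is_male = state.sex == "M"
    candidates = np.arange(n)
    ub = np.full(n, np.inf)
    # a male covering c of the F females contributes c/(2F); the per-male
    # mating cap therefore bounds male contributions directly
    ub[is_male] = max_per_male / (2.0 * len(females))
    ub[~is_male] = 0.0
    ub[females] = 0.5 / len(females)

    if config.scheme in ("MOCS-S", "MOCS-K"):
        S = _similarity_matrix(state, config, R, effects)
        if config.scheme == "MOCS-K":
            K = standardize(S)
            # zero-MSV individuals are excluded from K; keep the problem
            # at full size by embedding K and capping excluded males at 0
            kept = {e: k for k, e in enumerate(K.entities)}
            present = np.array(
                [i for i, e in enumerate(S.entities) if e in kept]
            )
            Q = np.zeros((n, n))
            Q[np.ix_(present, present)] = near_pd(K.values)
            absent = np.setdiff1d(candidates, present)
            ub[np.intersect1d(absent, np.flatnonzero(is_male))] = 0.0
            cap = q_bar if q_bar is not None else np.inf
        else:
            Q = near_pd(S.values / scale)
            cap = q_bar
    else:  # OCS-GRM
        G = mocs_mod.vanraden_grm(state.genotypes)
        Q = near_pd(G)
        cap = mocs_mod.inbreeding_constraint(G, config.delta_f)

    problem = mocs_mod.ContributionProblem(
        criterion=np.asarray(crit),
        Q=Q,
        q_bar=cap,
        is_male=is_male,
        q_kind=config.scheme.split("-")[-1],
        upper_bounds=ub,
        min_sires=config.min_sires,
        max_sires=config.max_sires,
        repair=False,
    )
    sol = mocs_mod.solve_contributions(problem)
    return sol.contributions[males] if sol.feasible else None
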