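"""Core genomic data structures and constructions.

This module holds the genetic map, phased genotypes and marker effects, and
the derived quantities every other module consumes:

* the within-family linkage-disequilibrium covariance matrix ``R`` whose
  entries decay exponentially with map distance under Haldane's mapping
  function (``rho_kl = exp(-2 d_kl) / 4``, block-diagonal by chromosome);
* parent-specific *signed* effect vectors ``m_i`` in which each marker effect
  carries the sign of the parent's linkage phase (and is zeroed at homozygous
  loci);
* breeding values as the inner product of genotype indicators with effects.

Allele coding: an allele value of 1 denotes the reference allele, 0 the
alternate.  The genotype indicator is ``c = h1 + h2 - 1`` (1 homozygous
reference, 0 heterozygous, -1 homozygous alternate) and the phase indicator is
``delta = h1 - h2`` (+1 reference on the first haplotype, -1 on the second,
0 homozygous).  All map distances are stored in Morgans.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticMap",
    "PhasedGenotypes",
    "MarkerEffects",
    "SignedEffects",
    "haldane",
    "inverse_haldane",
    "build_R",
    "signed_effects",
    "breeding_value",
]


def haldane(theta):
    """Map a recombination fraction to a distance in Morgans (Haldane).

    ``d = -0.5 * ln(1 - 2 theta)`` for ``theta`` in ``[0, 0.5)``.
    Accepts scalars or arrays.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -0.5 * np.log1p(-2.0 * theta)
    return float(d) if d.ndim == 0 else d


def inverse_haldane(d):
    """Map a distance in Morgans back to a recombination fraction.

    ``theta = (1 - exp(-2 d)) / 2`` for ``d >= 0``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    theta = 0.5 * -np.expm1(-2.0 * d)
    return float(theta) if theta.ndim == 0 else theta


@dataclass(frozen=True)
class GeneticMap:
    """Marker positions in Morgans, grouped by chromosome.

    Parameters
    ----------
    chromosome : array of chromosome labels, one per marker.
    position : array of map positions in **Morgans**, non-decreasing within
        each chromosome.
    marker_id : array of unique marker identifiers.
    """

    chromosome: np.ndarray
    position: np.ndarray
    marker_id: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "chromosome", np.asarray(self.chromosome))
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float)
        )
        object.__setattr__(self, "marker_id", np.asarray(self.marker_id))
        if not (
            len(self.chromosome) == len(self.position) == len(self.marker_id)
        ):
            raise ValueError("map fields must have equal length")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("map positions must be finite")
        ids, counts = np.unique(self.marker_id, return_counts=True)
        if np.any(counts > 1):
            raise ValueError(
                f"duplicate marker ids: {ids[counts > 1][:5].tolist()}"
            )
        for chrom in self.chromosomes:
            pos = self.position[self.chromosome == chrom]
            if np.any(np.diff(pos) < 0):
                raise ValueError(
                    f"positions on chromosome {chrom!r} are not sorted"
                )
            if np.any(np.diff(pos) == 0):
                warnings.warn(
                    f"co-located markers on chromosome {chrom!r} "
                    "(map distance 0, rho = 0.25 off-diagonal)",
                    stacklevel=2,
                )

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        _, idx = np.unique(self.chromosome, return_index=True)
        return [self.chromosome[i] for i in np.sort(idx)]

    def markers_on(self, chromosome) -> np.ndarray:
        """Indices (into the genome-wide marker order) on one chromosome."""
        idx = np.flatnonzero(self.chromosome == chromosome)
        if idx.size == 0:
            raise ValueError(f"chromosome {chromosome!r} not in map")
        return idx

    @classmethod
    def from_recombination_fractions(
        cls, theta, marker_id=None, chromosome="1"
    ) -> "GeneticMap":
        """Build a single-chromosome map from adjacent recombination
        fractions, converting them to cumulative Morgan positions via
        Haldane's function."""
        theta = np.asarray(theta, dtype=float)
        pos = np.concatenate([[0.0], np.cumsum(haldane(theta))])
        n = len(pos)
        if marker_id is None:
            marker_id = [f"m{k + 1}" for k in range(n)]
        return cls(np.repeat(chromosome, n), pos, np.asarray(marker_id))


@dataclass(frozen=True)
class PhasedGenotypes:
    """Phased biallelic genotypes for a set of individuals.

    ``haplotypes`` has shape ``(n_individuals, 2, n_markers)`` with entries
    in {0, 1}; 1 is the reference allele.  Sex labels, when present, are
    'M'/'F' strings.
    """

    haplotypes: np.ndarray
    sample_id: np.ndarray
    sex: np.ndarray | None = None

    def __post_init__(self):
        hap = np.asarray(self.haplotypes, dtype=np.int8)
        if hap.ndim != 3 or hap.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, markers)")
        if not np.isin(hap, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0 or 1")
        object.__setattr__(self, "haplotypes", hap)
        object.__setattr__(self, "sample_id", np.asarray(self.sample_id))
        if len(self.sample_id) != hap.shape[0]:
            raise ValueError("sample_id length mismatch")
        if self.sex is not None:
            sex = np.asarray(self.sex)
            if len(sex) != hap.shape[0]:
                raise ValueError("sex length mismatch")
            object.__setattr__(self, "sex", sex)

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def genotype_indicator(self) -> np.ndarray:
        """``c``: +1 hom-ref, 0 het, -1 hom-alt; shape (n, markers)."""
        return (
            self.haplotypes[:, 0, :] + self.haplotypes[:, 1, :] - 1
        ).astype(np.int8)

    @property
    def phase_indicator(self) -> np.ndarray:
        """``delta``: +1 ref on first haplotype, -1 on second, 0 homozygous."""
        return (
            self.haplotypes[:, 0, :] - self.haplotypes[:, 1, :]
        ).astype(np.int8)

    @property
    def dosage(self) -> np.ndarray:
        """Reference-allele dosage in {0, 1, 2}; shape (n, markers)."""
        return self.haplotypes.sum(axis=1)

    def index_of(self, sample) -> int:
        idx = np.flatnonzero(self.sample_id == sample)
        if idx.size == 0:
            raise KeyError(f"unknown sample {sample!r}")
        return int(idx[0])

    def subset(self, indices) -> "PhasedGenotypes":
        indices = np.asarray(indices)
        return PhasedGenotypes(
            self.haplotypes[indices],
            self.sample_id[indices],
            None if self.sex is None else self.sex[indices],
        )


@dataclass(frozen=True)
class MarkerEffects:
    """Additive allele-substitution effects, one row per trait.

    ``values`` has shape ``(n_traits, n_markers)`` in trait units per copy of
    the reference allele.  ``index_weights`` (optional) holds one economic
    weight per trait for aggregate-genotype calculations.
    """

    values: np.ndarray
    trait: tuple
    index_weights: np.ndarray | None = None

    def __post_init__(self):
        vals = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(vals)):
            raise ValueError("marker effects must be finite")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "trait", tuple(self.trait))
        if len(self.trait) != vals.shape[0]:
            raise ValueError("one trait name per effects row required")
        if self.index_weights is not None:
            a = np.asarray(self.index_weights, dtype=float)
            if a.shape != (vals.shape[0],):
                raise ValueError("index weights must have one entry per trait")
            object.__setattr__(self, "index_weights", a)

    @property
    def n_traits(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SignedEffects:
    """Parent-specific signed marker effects ``m_ik = delta_ik * m_k``.

    ``by_chromosome`` maps each chromosome label to a (traits x markers-on-c)
    matrix.  Entries are zero exactly at the parent's homozygous markers and
    at zero-effect markers; negating every entry (a haplotype swap) leaves
    every Mendelian sampling variance and |similarity| unchanged.
    """

    parent: object
    by_chromosome: dict = field(default_factory=dict)

    def chromosomes(self):
        return list(self.by_chromosome)

    def trait_row(self, trait_index: int) -> "SignedEffects":
        """Single-trait view (rows collapsed to one)."""
        return SignedEffects(
            self.parent,
            {
                c: m[trait_index : trait_index + 1]
                for c, m in self.by_chromosome.items()
            },
        )


def _check_alignment(genotypes: PhasedGenotypes, gmap: GeneticMap,
                     effects: MarkerEffects | None = None):
    if genotypes.n_markers != gmap.n_markers:
        raise ValueError(
            f"genotypes carry {genotypes.n_markers} markers but the map "
            f"carries {gmap.n_markers}"
        )
    if effects is not None and effects.n_markers != gmap.n_markers:
        raise ValueError(
            f"effects carry {effects.n_markers} markers but the map "
            f"carries {gmap.n_markers}"
        )


def build_R(gmap: GeneticMap, chromosome) -> np.ndarray:
    """Within-family LD covariance block for one chromosome.

    ``rho_kl = exp(-2 |pos_k - pos_l|) / 4``; diagonal exactly 0.25.  The
    matrix is parent-independent (the all-positive form): linkage phase is
    carried by the signed effect vectors instead, so one ``R`` per chromosome
    serves every parent and trait.
    """
    pos = gmap.position[gmap.markers_on(chromosome)]
    d = np.abs(pos[:, None] - pos[None, :])
    R = np.exp(-2.0 * d) / 4.0
    np.fill_diagonal(R, 0.25)
    return R


def build_R_all(gmap: GeneticMap) -> dict:
    """All per-chromosome R blocks, keyed by chromosome label.

    Built once and shared across parents and traits; markers on different
    chromosomes have zero covariance, so off-blocks are never materialised.
    """
    return {c: build_R(gmap, c) for c in gmap.chromosomes}


def signed_effects(
    genotypes: PhasedGenotypes,
    gmap: GeneticMap,
    effects: MarkerEffects,
    parent,
) -> SignedEffects:
    """Parent-specific signed effect matrix, split by chromosome."""
    _check_alignment(genotypes, gmap, effects)
    i = genotypes.index_of(parent)
    delta = genotypes.phase_indicator[i]  # (markers,)
    signed = effects.values * delta[None, :]  # (traits, markers)
    by_chrom = {
        c: signed[:, gmap.markers_on(c)] for c in gmap.chromosomes
    }
    return SignedEffects(parent, by_chrom)


def breeding_value(
    genotypes: PhasedGenotypes,
    gmap: GeneticMap,
    effects: MarkerEffects,
    parent=None,
) -> np.ndarray:
    """Breeding value ``b_i = c_i' m`` per trait.

    With ``parent=None`` returns the (individuals x traits) matrix for the
    whole population.
    """
    _check_alignment(genotypes, gmap, effects)
    c = genotypes.genotype_indicator.astype(float)
    if parent is not None:
        c = c[genotypes.index_of(parent)][None, :]
    bv = c @ effects.values.T
    return bv[0] if parent is not None else bv
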