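"""Mendelian sampling variances and covariances for gametes and zygotes.

The Mendelian sampling variance (MSV) of a parent is the variance among the
breeding values of the gametes it can produce, driven by segregation at its
heterozygous loci.  With a parent-specific signed effect vector ``m_i``
(phase-signed, zeroed at homozygous loci) and the shared within-family LD
matrix ``R`` the gamete MSV is the quadratic form ``m_i' R m_i`` summed over
chromosomes.  For several traits the quadratic form generalises to
``V_i = sum_c M_ic R_c M_ic'`` whose diagonal holds per-trait MSVs and whose
off-diagonal holds Mendelian sampling covariances between traits; an index
weight vector ``a`` collapses it to the aggregate-genotype MSV ``a' V_i a``.
Zygote quantities are the sums of the two parental gamete quantities because
the two meioses are independent.

A legacy formulation that bakes phase signs and homozygosity into a
parent-specific matrix ``R_i`` (so the MSV is ``m' R_i m`` with the raw
population effects) is kept in :mod:`msvtools.validation` purely as an
internal cross-check of the algebraic equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_model import SignedEffects

__all__ = [
    "MendelianCovariance",
    "gamete_msv",
    "multitrait_V",
    "aggregate_msv",
    "zygote_msv",
    "zygote_V",
    "zygote_aggregate",
]

PSD_TOL = 1e-10


@dataclass(frozen=True)
class MendelianCovariance:
    """Traits x traits Mendelian covariance matrix for a gamete or zygote.

    ``values`` is symmetric positive semidefinite (within floating point);
    its diagonal holds the per-trait MSVs, its off-diagonal the Mendelian
    sampling covariances.  ``owner`` is a parent id (gamete role) or a
    parent-id pair (zygote role).
    """

    values: np.ndarray
    role: str
    owner: object

    def __post_init__(self):
        V = np.atleast_2d(np.asarray(self.values, dtype=float))
        if V.shape[0] != V.shape[1]:
            raise ValueError("Mendelian covariance must be square")
        if not np.allclose(V, V.T, atol=1e-12):
            raise ValueError("Mendelian covariance must be symmetric")
        if self.role not in ("gamete", "zygote"):
            raise ValueError("role must be 'gamete' or 'zygote'")
        object.__setattr__(self, "values", V)

    @property
    def msv(self) -> np.ndarray:
        """Per-trait MSVs (diagonal), clamped at 0 for tiny negatives."""
        d = np.diag(self.values).copy()
        d[(d < 0) & (d > -PSD_TOL)] = 0.0
        return d


def _pair_quadratic(mi: SignedEffects, mj: SignedEffects, R: dict,
                    absolute: bool = False) -> np.ndarray:
    """``sum_c M_ic R_c M_jc'`` (traits x traits), optionally with the
    absolute value taken per chromosome before summing."""
    chroms = mi.chromosomes()
    if chroms != mj.chromosomes():
        raise ValueError("parents cover different chromosomes")
    total = None
    for c in chroms:
        Mi, Mj = mi.by_chromosome[c], mj.by_chromosome[c]
        Rc = R[c]
        if Mi.shape[1] != Rc.shape[0] or Mj.shape[1] != Rc.shape[0]:
            raise ValueError(
                f"chromosome {c!r}: effects/R dimension mismatch "
                f"({Mi.shape[1]}, {Mj.shape[1]} vs {Rc.shape[0]})"
            )
        term = Mi @ Rc @ Mj.T
        if absolute:
            term = np.abs(term)
        total = term if total is None else total + term
    if total is None:
        raise ValueError("no chromosomes present")
    return total


def gamete_msv(m_i: SignedEffects, R: dict, trait: int = 0) -> float:
    """Single-trait gamete MSV ``sum_c m_ic' R_c m_ic``.

    Always >= 0 and invariant to a global sign flip of ``m_i`` (haplotype
    order).
    """
    mi = m_i.trait_row(trait)
    return float(_pair_quadratic(mi, mi, R)[0, 0])


def multitrait_V(M_i: SignedEffects, R: dict) -> MendelianCovariance:
    """Gametic Mendelian covariance matrix ``V_i = sum_c M_ic R_c M_ic'``."""
    V = _pair_quadratic(M_i, M_i, R)
    V = 0.5 * (V + V.T)  # symmetrise against roundoff
    return MendelianCovariance(V, "gamete", M_i.parent)


def aggregate_msv(V: MendelianCovariance, a) -> float:
    """Aggregate-genotype MSV ``a' V a`` for index weights ``a``."""
    a = np.asarray(a, dtype=float)
    if a.shape != (V.values.shape[0],):
        raise ValueError("index weights must have one entry per trait")
    return float(a @ V.values @ a)


def population_msv(genotypes, gmap, effects, R: dict,
                   trait: int = 0) -> np.ndarray:
    """Gamete MSVs for every individual at once (vectorised).

    Equivalent to :func:`gamete_msv` per parent; the signed effect rows for
    all parents are formed in one array per chromosome, so the cost is a
    handful of matrix products instead of a Python loop.
    """
    delta = genotypes.phase_indicator.astype(float)
    m = effects.values[trait]
    out = np.zeros(genotypes.n_individuals)
    for c in gmap.chromosomes:
        idx = gmap.markers_on(c)
        W = delta[:, idx] * m[idx][None, :]
        out += np.einsum("ik,ik->i", W @ R[c], W)
    return out


def zygote_msv(m_i: SignedEffects, m_j: SignedEffects, R: dict,
               trait: int = 0) -> float:
    """Zygote MSV: exact sum of the two parental gamete MSVs."""
    return gamete_msv(m_i, R, trait) + gamete_msv(m_j, R, trait)


def zygote_V(M_i: SignedEffects, M_j: SignedEffects,
             R: dict) -> MendelianCovariance:
    """Zygotic Mendelian covariance matrix ``V_ij = V_i + V_j``."""
    V = multitrait_V(M_i, R).values + multitrait_V(M_j, R).values
    return MendelianCovariance(V, "zygote", (M_i.parent, M_j.parent))


def zygote_aggregate(V_ij: MendelianCovariance, a) -> float:
    """Aggregate-genotype zygote MSV ``a' V_ij a``."""
    return aggregate_msv(V_ij, a)
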