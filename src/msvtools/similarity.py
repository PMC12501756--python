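"""Trait-specific haplotype-similarity matrices between parents.

The similarity between parents i and j is the bilinear form of their
phase-signed effect vectors with the within-family LD matrix,
``s_ij = |m_ic' R_c m_jc|`` summed over chromosomes.  It is large when the
two parents are heterozygous for markers with large effects in the same
linkage phase on shared chromosome segments, and a parent's similarity to
itself equals its Mendelian sampling variance.  The absolute value is taken
per chromosome so that the measure does not depend on the arbitrary order in
which each parent's haplotypes are stored.

Assembled over a set of parents these similarities form the matrix ``S``
(MSVs on the diagonal); dividing rows and columns by the Mendelian standard
deviations standardises it to ``K`` with unit diagonal and off-diagonals in
[0, 1] (Cauchy-Schwarz).  Zygotic variants operate on parent *pairs*:
``s_ij,uv = |m_i' R m_u| + |m_j' R m_v|`` per chromosome, matching sire with
sire and dam with dam.

``S`` is positive semidefinite in theory but can come out indefinite in
practice (more parents than informative markers, chromosome-wise
rank deficiency); :func:`near_pd` repairs it by Higham's alternating
projections before it is used in a quadratic constraint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np

from .genome_model import (
    GeneticMap,
    MarkerEffects,
    PhasedGenotypes,
    SignedEffects,
    build_R_all,
    signed_effects,
)
from .msv import _pair_quadratic

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "pairwise_similarity",
    "aggregate_similarity",
    "zygotic_similarity",
    "build_S",
    "standardize",
    "near_pd",
    "shared_heterozygosity",
    "weighted_shared_effects",
]

ZERO_MSV_EPS = 1e-12


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square similarity matrix over parents (gametic) or parent pairs
    (zygotic).

    ``kind`` is 'S' (raw; diagonal = MSVs) or 'K' (standardised; unit
    diagonal).  ``entities`` holds parent ids, or (sire, dam) tuples in
    zygotic mode.  ``trait`` is a trait name or 'aggregate'.
    """

    entities: tuple
    values: np.ndarray
    kind: str
    trait: str

    def __post_init__(self):
        V = np.atleast_2d(np.asarray(self.values, dtype=float))
        if V.shape[0] != V.shape[1] or V.shape[0] != len(self.entities):
            raise ValueError("matrix/entity dimension mismatch")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if self.kind not in ("S", "K"):
            raise ValueError("kind must be 'S' or 'K'")
        object.__setattr__(self, "values", V)
        object.__setattr__(self, "entities", tuple(self.entities))

    @property
    def n(self) -> int:
        return len(self.entities)

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle off-diagonal values as a flat array."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def pairwise_similarity(m_i: SignedEffects, m_j: SignedEffects, R: dict,
                        trait: int = 0) -> float:
    """Gametic similarity ``sum_c |m_ic' R_c m_jc|`` for one trait."""
    s = _pair_quadratic(m_i.trait_row(trait), m_j.trait_row(trait), R,
                        absolute=True)
    return float(s[0, 0])


def aggregate_similarity(M_i: SignedEffects, M_j: SignedEffects, R: dict,
                         a) -> float:
    """Aggregate-genotype similarity ``sum_c |a' M_ic R_c M_jc' a|``.

    The absolute value is applied per chromosome, the same convention as the
    single-trait form, so the result is invariant to haplotype order.
    """
    a = np.asarray(a, dtype=float)
    total = 0.0
    chroms = M_i.chromosomes()
    if chroms != M_j.chromosomes():
        raise ValueError("parents cover different chromosomes")
    for c in chroms:
        Mi, Mj = M_i.by_chromosome[c], M_j.by_chromosome[c]
        if a.shape != (Mi.shape[0],):
            raise ValueError("index weights must have one entry per trait")
        total += abs(float(a @ (Mi @ R[c] @ Mj.T) @ a))
    return total


def zygotic_similarity(m_i, m_j, m_u, m_v, R: dict, trait: int = 0,
                       a=None) -> float:
    """Similarity between the zygotes of pairs (i, j) and (u, v).

    Matches the first parent of each pair with the first of the other
    (sire-with-sire, dam-with-dam) and sums the two per-chromosome absolute
    bilinear forms.  With weights ``a`` the aggregate-genotype form is used.
    Its diagonal ``s_ij,ij`` equals the zygote MSV.
    """
    if a is not None:
        return (aggregate_similarity(m_i, m_u, R, a)
                + aggregate_similarity(m_j, m_v, R, a))
    return (pairwise_similarity(m_i, m_u, R, trait)
            + pairwise_similarity(m_j, m_v, R, trait))


def build_S(
    genotypes: PhasedGenotypes,
    gmap: GeneticMap,
    effects: MarkerEffects,
    mode: str = "gametic",
    trait=0,
    parents=None,
    pairs=None,
    R: dict | None = None,
) -> SimilarityMatrix:
    """Assemble the similarity matrix S over parents or parent pairs.

    Parameters
    ----------
    mode : 'gametic' (entities are parents) or 'zygotic' (entities are
        (sire, dam) pairs supplied via ``pairs``).
    trait : trait index, or 'aggregate' to use the effects' index weights.
    parents : parent ids to include (default: all individuals).
    R : optional pre-built per-chromosome LD blocks (cached by callers that
        rebuild S every generation).
    """
    if R is None:
        R = build_R_all(gmap)
    aggregate = trait == "aggregate"
    if aggregate:
        if effects.index_weights is None:
            raise ValueError("aggregate mode requires index weights")
        a = effects.index_weights
        label = "aggregate"
    else:
        a = None
        label = str(effects.trait[trait])

    if mode == "gametic":
        ids = tuple(genotypes.sample_id if parents is None else parents)
        if len(ids) == 0:
            raise ValueError("empty population")
        # vectorised: per chromosome, all parents' signed effect rows at
        # once; S accumulates |W_c R_c W_c'| (aggregate mode folds the
        # index weights into the rows first, a' M R M' a = (a'M) R (M'a))
        rows = np.array([genotypes.index_of(p) for p in ids])
        delta = genotypes.phase_indicator[rows].astype(float)
        weights = (a @ effects.values if aggregate
                   else effects.values[trait])
        S = np.zeros((len(ids), len(ids)))
        for c in gmap.chromosomes:
            idx = gmap.markers_on(c)
            W = delta[:, idx] * weights[idx][None, :]
            S += np.abs(W @ R[c] @ W.T)
        S = 0.5 * (S + S.T)
        return SimilarityMatrix(ids, S, "S", label)
    elif mode == "zygotic":
        if not pairs:
            raise ValueError("zygotic mode requires parent pairs")
        entities = tuple(tuple(p) for p in pairs)
        uniq = sorted({p for pair in entities for p in pair},
                      key=lambda p: str(p))
        cache = {p: signed_effects(genotypes, gmap, effects, p) for p in uniq}

        def sim(x, y):
            i, j = entities[x]
            u, v = entities[y]
            return zygotic_similarity(cache[i], cache[j], cache[u], cache[v],
                                      R, trait=0 if aggregate else trait,
                                      a=a)
    else:
        raise ValueError("mode must be 'gametic' or 'zygotic'")

    n = len(entities)
    S = np.zeros((n, n))
    for x, y in combinations_with_replacement(range(n), 2):
        S[x, y] = S[y, x] = sim(x, y)
    return SimilarityMatrix(entities, S, "S", label)


def standardize(S: SimilarityMatrix, eps: float = ZERO_MSV_EPS
                ) -> SimilarityMatrix:
    """Standardise S to K = D^-1 S D^-1 with D the diagonal matrix of
    Mendelian standard deviations (sqrt of the diagonal of S).

    Entities whose MSV falls below ``eps`` carry no Mendelian sampling
    information and would divide by zero; they are dropped with a warning.
    """
    if S.kind != "S":
        raise ValueError("standardize expects a raw S matrix")
    d = np.diag(S.values)
    keep = d > eps
    if not np.all(keep):
        dropped = [S.entities[k] for k in np.flatnonzero(~keep)]
        logger.warning(
            "excluding %d zero-MSV entities from K: %s",
            len(dropped), dropped,
        )
    if not np.any(keep):
        raise ValueError("no entity has MSV above eps; K is undefined")
    idx = np.flatnonzero(keep)
    sub = S.values[np.ix_(idx, idx)]
    inv_sd = 1.0 / np.sqrt(np.diag(sub))
    K = sub * np.outer(inv_sd, inv_sd)
    np.fill_diagonal(K, 1.0)
    return SimilarityMatrix(
        tuple(S.entities[k] for k in idx), K, "K", S.trait
    )


def near_pd(matrix: np.ndarray, tolerance: float = 1e-8,
            max_iterations: int = 100) -> np.ndarray:
    """Nearest positive semidefinite matrix by alternating projections
    (Higham) with eigenvalue clipping.

    Idempotent on already-PSD input (returned unchanged within 1e-12); the
    output's smallest eigenvalue is >= -tolerance times its largest.
    """
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("near_pd expects a square matrix")
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("near_pd expects a symmetric matrix")
    A = 0.5 * (A + A.T)
    w = np.linalg.eigvalsh(A)
    scale = max(abs(w.max()), 1.0)
    if w.min() >= -tolerance * scale:
        return A
    logger.warning(
        "repairing indefinite matrix (min eigenvalue %.3e)", w.min()
    )
    # Unconstrained alternating projection onto the PSD cone reduces to
    # eigenvalue clipping; iterate to absorb roundoff reintroduced by the
    # reconstruction, as R's nearPD does with corr=FALSE.
    X = A
    for _ in range(max_iterations):
        w, Q = np.linalg.eigh(X)
        if w.min() >= -tolerance * scale:
            break
        X = (Q * np.clip(w, 0.0, None)) @ Q.T
        X = 0.5 * (X + X.T)
    return X


def shared_heterozygosity(genotypes: PhasedGenotypes, parent_i,
                          parent_j) -> int:
    """Number of markers heterozygous in *both* parents."""
    delta = genotypes.phase_indicator
    di = delta[genotypes.index_of(parent_i)]
    dj = delta[genotypes.index_of(parent_j)]
    return int(np.count_nonzero((di != 0) & (dj != 0)))


def weighted_shared_effects(genotypes: PhasedGenotypes,
                            effects: MarkerEffects, parent_i, parent_j,
                            trait: int = 0) -> float:
    """Sum of squared marker effects over markers heterozygous in both
    parents — the unlinked-marker interpretation of similarity (times 4)."""
    delta = genotypes.phase_indicator
    di = delta[genotypes.index_of(parent_i)]
    dj = delta[genotypes.index_of(parent_j)]
    both = (di != 0) & (dj != 0)
    m = effects.values[trait]
    return float(np.sum(m[both] ** 2))
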