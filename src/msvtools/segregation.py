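"""Exhaustive enumeration of gamete segregation patterns on one chromosome.

A segregation pattern labels, locus by locus, whether a gamete received the
allele on the parent's first (A) or second (B) haplotype.  With ``L`` loci
there are ``2**L`` patterns; the probability of a pattern is one half (the
starting haplotype) times, for each adjacent marker interval, the
recombination fraction ``theta`` if the source switches and ``1 - theta`` if
it does not.  The breeding value a pattern transmits is half the signed sum
of marker effects, the sign given by which allele (reference or alternate)
sits on the transmitted haplotype.

Enumerating the full distribution gives *exact* means, variances and
covariances of gamete breeding values, which makes this module the
ground-truth oracle for the closed-form quadratic expressions elsewhere in
the package.  Crucially, the covariance between two parents' gametes is taken
over the *matched-pattern* (univariate, conditional) distribution — each
pattern paired with the same pattern in the other parent — not over the joint
distribution of two independent meioses, which would be identically zero.

This module is exact or it refuses: no sampling, hard cap at 20 loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SegregationPattern",
    "enumerate_patterns",
    "oracle_moments",
    "oracle_zygote",
    "MAX_LOCI",
]

MAX_LOCI = 20


@dataclass(frozen=True)
class SegregationPattern:
    """One pattern: per-locus source labels, probability, and the gamete
    breeding value it transmits for each parent."""

    sources: tuple  # 'A'/'B' per locus
    probability: float
    breeding_values: tuple  # one per parent


def _pattern_probabilities(theta: np.ndarray, L: int) -> np.ndarray:
    """Probabilities of all 2**L patterns, pattern w encoded as a bitmask
    (bit k set = haplotype B at locus k).  Log-space product to stay exact
    to float precision near L = 20."""
    masks = np.arange(2**L, dtype=np.uint32)
    bits = ((masks[:, None] >> np.arange(L)[None, :]) & 1).astype(np.int8)
    switches = bits[:, 1:] != bits[:, :-1]  # (patterns, L-1)
    with np.errstate(divide="ignore"):
        log_theta = np.log(theta)
        log_keep = np.log1p(-theta)
    logp = np.where(switches, log_theta[None, :], log_keep[None, :]).sum(
        axis=1
    ) + np.log(0.5)
    return bits, np.exp(logp)


def _gamete_bv(bits: np.ndarray, haplotypes: np.ndarray,
               m: np.ndarray) -> np.ndarray:
    """Breeding values transmitted by each pattern for one parent.

    ``haplotypes`` is (2, L) with 1 = reference allele; a transmitted
    reference allele contributes +m_k/2, an alternate allele -m_k/2.
    """
    transmitted = np.where(bits == 0, haplotypes[0][None, :],
                           haplotypes[1][None, :])
    return 0.5 * ((2 * transmitted - 1).astype(float) @ m)


def enumerate_patterns(theta, parents, m) -> list[SegregationPattern]:
    """Enumerate all segregation patterns for single-chromosome parents.

    Parameters
    ----------
    theta : adjacent recombination fractions, length L-1, each in [0, 0.5).
    parents : list of (2, L) haplotype arrays (1 = reference allele).
    m : marker effects, length L.
    """
    theta = np.asarray(theta, dtype=float)
    m = np.asarray(m, dtype=float)
    L = len(m)
    if L > MAX_LOCI:
        raise ValueError(
            f"{L} loci would enumerate 2^{L} patterns; cap is {MAX_LOCI}"
        )
    if theta.shape != (L - 1,):
        raise ValueError("need one recombination fraction per interval")
    if np.any(theta < 0) or np.any(theta >= 0.5):
        raise ValueError("recombination fractions must lie in [0, 0.5)")
    haps = [np.asarray(h, dtype=np.int8) for h in parents]
    for h in haps:
        if h.shape != (2, L):
            raise ValueError("each parent must be a (2, L) haplotype array")

    bits, probs = _pattern_probabilities(theta, L)
    bvs = np.column_stack([_gamete_bv(bits, h, m) for h in haps])
    out = []
    for w in range(2**L):
        sources = tuple("B" if b else "A" for b in bits[w])
        out.append(
            SegregationPattern(sources, float(probs[w]), tuple(bvs[w]))
        )
    return out


def oracle_moments(patterns: list[SegregationPattern]):
    """Exact mean and variance per parent and matched-pattern covariance
    matrix across parents.

    Returns ``(mean, cov)`` where ``mean`` has one entry per parent (always 0
    by the A/B-swap symmetry) and ``cov[i, j] = E[b_i b_j]`` over the shared
    pattern distribution; the diagonal holds the exact MSVs.
    """
    p = np.array([w.probability for w in patterns])
    b = np.array([w.breeding_values for w in patterns])  # (patterns, parents)
    mean = p @ b
    cov = (b * p[:, None]).T @ b - np.outer(mean, mean)
    return mean, cov


def oracle_zygote(patterns, pair_ij=(0, 1), pair_uv=(0, 1)):
    """Zygote MSV of pair ij and pattern-matched similarity to pair uv.

    The zygote MSV is computed by brute force over the *joint* distribution
    of two independent parental pattern draws (every pattern of parent i
    against every pattern of parent j), since a zygote combines two
    independent meioses.  The similarity between two pairs instead matches
    patterns within each parental slot (i with u, j with v) — the
    conditional, univariate construction — and sums the two matched
    covariances, each in absolute value.  Returns
    ``(zygote_msv_ij, similarity_ij_uv)``.
    """
    p = np.array([w.probability for w in patterns])
    b = np.array([w.breeding_values for w in patterns])
    if len(p) ** 2 > 2**MAX_LOCI:
        raise ValueError("joint enumeration exceeds the 2^20 cap")
    i, j = pair_ij
    u, v = pair_uv
    # joint over independent draws: b_zygote = b_i(w) + b_j(x)
    pj = np.outer(p, p)
    bz = b[:, i][:, None] + b[None, :, j]
    mean = float((pj * bz).sum())
    msv_ij = float((pj * bz**2).sum()) - mean**2
    # matched-pattern covariances per parental slot
    _, cov = oracle_moments(patterns)
    sim = abs(cov[i, u]) + abs(cov[j, v])
    return msv_ij, float(sim)
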