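"""Legacy reference formulation of the gamete MSV, kept as a cross-check.

The original analytical route builds a *parent-specific* covariance matrix
``R_i`` whose element (k, l) is ``+/- exp(-2 d_kl) / 4`` with the sign set by
the parent's linkage phase between markers k and l, and with rows/columns of
homozygous markers zeroed; the MSV is then ``m' R_i m`` with the raw
population effect vector.  This is algebraically identical to the fast route
``m_i' R m_i`` (phase signs moved into the effect vector), but costs a fresh
O(p^2) matrix per parent.  It is retained here, outside the public API, so
tests can assert the equivalence of the two routes.
"""

from __future__ import annotations

import numpy as np

from .genome_model import GeneticMap, MarkerEffects, PhasedGenotypes

__all__ = ["parent_R_i", "gamete_msv_reference"]


def parent_R_i(gmap: GeneticMap, delta: np.ndarray, chromosome) -> np.ndarray:
    """Parent-specific signed within-family LD block for one chromosome.

    ``delta`` is the parent's genome-wide phase-indicator vector.  Marker
    pairs in coupling phase (same haplotype carries the reference allele at
    both) get a positive sign, repulsion pairs a negative sign; homozygous
    markers are zeroed out entirely.
    """
    idx = gmap.markers_on(chromosome)
    pos = gmap.position[idx]
    dc = delta[idx].astype(float)
    n = len(idx)
    Ri = np.empty((n, n))
    for k in range(n):
        for l in range(n):
            if dc[k] == 0 or dc[l] == 0:
                Ri[k, l] = 0.0
                continue
            rho = np.exp(-2.0 * abs(pos[k] - pos[l])) / 4.0
            Ri[k, l] = rho if dc[k] == dc[l] else -rho
    return Ri


def gamete_msv_reference(
    genotypes: PhasedGenotypes,
    gmap: GeneticMap,
    effects: MarkerEffects,
    parent,
    trait: int = 0,
) -> float:
    """Gamete MSV via the parent-specific matrix route ``m' R_i m``."""
    i = genotypes.index_of(parent)
    delta = genotypes.phase_indicator[i]
    m = effects.values[trait]
    total = 0.0
    for c in gmap.chromosomes:
        idx = gmap.markers_on(c)
        Ri = parent_R_i(gmap, delta, c)
        mc = m[idx]
        total += float(mc @ Ri @ mc)
    return total
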