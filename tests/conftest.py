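import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("repro")

from msvtools.genome_model import (  # noqa: E402
    GeneticMap,
    MarkerEffects,
    PhasedGenotypes,
    build_R_all,
)

# worked three-marker example: two parents, theta = (0.1, 0.2),
# effects (1, 0.2, 0.02); parent 1 carries the reference allele on its
# whole first haplotype, parent 2 on loci 1 and 3 only
TABLE_THETA = (0.1, 0.2)
TABLE_EFFECTS = (1.0, 0.2, 0.02)
TABLE_HAP1 = np.array([[1, 1, 1], [0, 0, 0]], dtype=np.int8)
TABLE_HAP2 = np.array([[1, 0, 1], [0, 1, 0]], dtype=np.int8)

MSV_PARENT1 = 0.3461
MSV_PARENT2 = 0.1837
SIMILARITY_12 = 0.2449


@pytest.fixture(scope="session")
def worked_example():
    gmap = GeneticMap.from_recombination_fractions(TABLE_THETA)
    geno = PhasedGenotypes(
        np.stack([TABLE_HAP1, TABLE_HAP2]), np.array(["p1", "p2"])
    )
    eff = MarkerEffects([list(TABLE_EFFECTS)], ("trait",))
    return gmap, geno, eff


@pytest.fixture(scope="session")
def worked_R(worked_example):
    gmap, _, _ = worked_example
    return build_R_all(gmap)


def random_instance(rng, max_markers=12, max_chromosomes=3, n_parents=2,
                    n_traits=1):
    """Random small phased population with map and effects, for
    property tests against the enumeration oracle."""
    n_chrom = rng.integers(1, max_chromosomes + 1)
    markers_per = rng.integers(1, max_markers // n_chrom + 1, size=n_chrom)
    chroms, pos = [], []
    for c, m in enumerate(markers_per):
        chroms.extend([str(c + 1)] * m)
        p = np.sort(rng.uniform(0, 1.5, size=m))
        pos.extend(p)
    n_markers = int(markers_per.sum())
    gmap = GeneticMap(
        np.array(chroms), np.array(pos),
        np.array([f"m{k}" for k in range(n_markers)]),
    )
    hap = rng.integers(0, 2, size=(n_parents, 2, n_markers)).astype(np.int8)
    geno = PhasedGenotypes(
        hap, np.array([f"p{k}" for k in range(n_parents)])
    )
    eff = MarkerEffects(
        rng.normal(0, 1, size=(n_traits, n_markers)),
        tuple(f"t{k}" for k in range(n_traits)),
    )
    return gmap, geno, eff
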