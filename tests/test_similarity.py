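from itertools import product

import numpy as np
import pytest

from msvtools.genome_model import (
    GeneticMap,
    MarkerEffects,
    PhasedGenotypes,
    build_R_all,
    signed_effects,
)
from msvtools.msv import gamete_msv, zygote_msv
from msvtools.similarity import (
    build_S,
    near_pd,
    pairwise_similarity,
    aggregate_similarity,
    shared_heterozygosity,
    standardize,
    weighted_shared_effects,
    zygotic_similarity,
)

from .conftest import (
    MSV_PARENT1,
    MSV_PARENT2,
    SIMILARITY_12,
    random_instance,
)


@pytest.fixture
def signed(worked_example):
    gmap, geno, eff = worked_example
    return {p: signed_effects(geno, gmap, eff, p) for p in ("p1", "p2")}


class TestPairwise:
    def test_worked_example_value(self, signed, worked_R):
        assert pairwise_similarity(
            signed["p1"], signed["p2"], worked_R
        ) == pytest.approx(SIMILARITY_12, abs=5e-5)

    def test_self_similarity_equals_msv(self, signed, worked_R):
        assert pairwise_similarity(
            signed["p1"], signed["p1"], worked_R
        ) == pytest.approx(gamete_msv(signed["p1"], worked_R))

    def test_monozygotic_twins_standardise_to_one(self, worked_example,
                                                  worked_R):
        gmap, geno, eff = worked_example
        twin = PhasedGenotypes(
            np.stack([geno.haplotypes[0], geno.haplotypes[0][::-1]]),
            np.array(["a", "b"]),
        )
        S = build_S(twin, gmap, eff)
        K = standardize(S)
        assert K.values[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_haplotype_order_invariance_exhaustive(self):
        # flip each parent's haplotypes per chromosome in all combinations
        rng = np.random.default_rng(31)
        gmap, geno, eff = random_instance(
            rng, max_markers=9, max_chromosomes=3, n_parents=2
        )
        R = build_R_all(gmap)
        chroms = gmap.chromosomes
        base = None
        for flips in product([False, True],
                             repeat=2 * len(chroms)):
            hap = geno.haplotypes.copy()
            k = 0
            for p in range(2):
                for c in chroms:
                    if flips[k]:
                        idx = gmap.markers_on(c)
                        hap[p, :, idx] = hap[p, ::-1, idx]
                    k += 1
            flipped = PhasedGenotypes(hap, geno.sample_id)
            m0 = signed_effects(flipped, gmap, eff, "p0")
            m1 = signed_effects(flipped, gmap, eff, "p1")
            val = (
                pairwise_similarity(m0, m1, R),
                gamete_msv(m0, R),
                gamete_msv(m1, R),
            )
            if base is None:
                base = val
            else:
                assert val == pytest.approx(base, abs=1e-12)

    def test_cauchy_schwarz(self):
        rng = np.random.default_rng(32)
        for _ in range(30):
            gmap, geno, eff = random_instance(rng, n_parents=2)
            R = build_R_all(gmap)
            m0 = signed_effects(geno, gmap, eff, "p0")
            m1 = signed_effects(geno, gmap, eff, "p1")
            s = pairwise_similarity(m0, m1, R)
            bound = np.sqrt(gamete_msv(m0, R) * gamete_msv(m1, R))
            assert s <= bound + 1e-10

    def test_cholesky_view_matches_per_chromosome_term(self):
        # with R = LL', the dot product of L m_i and L m_j equals the
        # unsigned bilinear contribution of that chromosome
        rng = np.random.default_rng(33)
        gmap, geno, eff = random_instance(
            rng, max_markers=8, max_chromosomes=1, n_parents=2
        )
        R = build_R_all(gmap)["1"]
        m0 = signed_effects(geno, gmap, eff, "p0").by_chromosome["1"][0]
        m1 = signed_effects(geno, gmap, eff, "p1").by_chromosome["1"][0]
        L = np.linalg.cholesky(R + 1e-12 * np.eye(len(R)))
        assert (L.T @ m0) @ (L.T @ m1) == pytest.approx(
            float(m0 @ R @ m1), abs=1e-8
        )


class TestAggregateSimilarity:
    def test_unit_weight_reduces_to_pairwise(self, signed, worked_R):
        assert aggregate_similarity(
            signed["p1"], signed["p2"], worked_R, [1.0]
        ) == pytest.approx(
            pairwise_similarity(signed["p1"], signed["p2"], worked_R)
        )

    def test_zero_weights_give_zero(self, signed, worked_R):
        assert aggregate_similarity(
            signed["p1"], signed["p2"], worked_R, [0.0]
        ) == 0.0

    def test_bilinearity_on_proportional_rows(self, worked_example,
                                              worked_R):
        gmap, geno, _ = worked_example
        eff2 = MarkerEffects(
            [[1.0, 0.2, 0.02], [2.0, 0.4, 0.04]], ("t1", "t2")
        )
        Mi = signed_effects(geno, gmap, eff2, "p1")
        Mj = signed_effects(geno, gmap, eff2, "p2")
        single = pairwise_similarity(
            Mi.trait_row(0), Mj.trait_row(0), worked_R
        )
        # weights (1, 1) on rows (m, 2m): (1 + 2)^2 = 9x the single trait
        assert aggregate_similarity(
            Mi, Mj, worked_R, [1.0, 1.0]
        ) == pytest.approx(9 * single, abs=1e-10)


class TestZygotic:
    def test_pair_vs_itself_is_zygote_msv(self, signed, worked_R):
        s = zygotic_similarity(
            signed["p1"], signed["p2"], signed["p1"], signed["p2"],
            worked_R,
        )
        assert s == pytest.approx(
            zygote_msv(signed["p1"], signed["p2"], worked_R)
        )
        assert s == pytest.approx(MSV_PARENT1 + MSV_PARENT2, abs=1e-4)

    def test_homozygous_other_pair_gives_zero(self, worked_example,
                                              signed, worked_R):
        gmap, _, eff = worked_example
        hom = PhasedGenotypes(
            np.ones((1, 2, 3), dtype=np.int8), np.array(["h"])
        )
        mh = signed_effects(hom, gmap, eff, "h")
        assert zygotic_similarity(
            signed["p1"], signed["p2"], mh, mh, worked_R
        ) == 0.0

    def test_decomposes_into_pairwise_terms(self):
        rng = np.random.default_rng(34)
        gmap, geno, eff = random_instance(rng, n_parents=4)
        R = build_R_all(gmap)
        m = [signed_effects(geno, gmap, eff, p) for p in geno.sample_id]
        assert zygotic_similarity(m[0], m[1], m[2], m[3], R) == (
            pytest.approx(
                pairwise_similarity(m[0], m[2], R)
                + pairwise_similarity(m[1], m[3], R)
            )
        )


class TestBuildS:
    def test_worked_example_matrix(self, worked_example):
        gmap, geno, eff = worked_example
        S = build_S(geno, gmap, eff)
        assert S.values == pytest.approx(
            np.array([[MSV_PARENT1, SIMILARITY_12],
                      [SIMILARITY_12, MSV_PARENT2]]),
            abs=5e-5,
        )

    def test_single_parent_matrix_is_msv(self, worked_example, worked_R):
        gmap, geno, eff = worked_example
        S = build_S(geno, gmap, eff, parents=["p1"])
        assert S.values[0, 0] == pytest.approx(
            gamete_msv(signed_effects(geno, gmap, eff, "p1"), worked_R)
        )

    def test_parent_permutation_permutes_matrix(self, worked_example):
        gmap, geno, eff = worked_example
        S = build_S(geno, gmap, eff, parents=["p1", "p2"])
        P = build_S(geno, gmap, eff, parents=["p2", "p1"])
        assert P.values == pytest.approx(S.values[::-1, ::-1])

    def test_zygotic_diagonal_is_zygote_msv(self):
        rng = np.random.default_rng(35)
        gmap, geno, eff = random_instance(rng, n_parents=4)
        R = build_R_all(gmap)
        pairs = [("p0", "p1"), ("p2", "p3")]
        Z = build_S(geno, gmap, eff, mode="zygotic", pairs=pairs)
        m = {p: signed_effects(geno, gmap, eff, p)
             for p in geno.sample_id}
        assert Z.values[0, 0] == pytest.approx(
            zygote_msv(m["p0"], m["p1"], R)
        )
        assert Z.values[1, 1] == pytest.approx(
            zygote_msv(m["p2"], m["p3"], R)
        )

    def test_empty_population_rejected(self, worked_example):
        gmap, geno, eff = worked_example
        with pytest.raises(ValueError):
            build_S(geno, gmap, eff, parents=[])


class TestStandardize:
    def test_worked_example_value(self, worked_example):
        gmap, geno, eff = worked_example
        K = standardize(build_S(geno, gmap, eff))
        assert K.values[0, 1] == pytest.approx(0.9714, abs=1e-3)
        assert np.diag(K.values) == pytest.approx([1.0, 1.0])

    def test_random_populations_unit_diag_and_bounded(self):
        rng = np.random.default_rng(36)
        for _ in range(10):
            gmap, geno, eff = random_instance(rng, n_parents=6)
            S = build_S(geno, gmap, eff)
            if np.diag(S.values).min() <= 1e-12:
                continue
            K = standardize(S)
            assert np.allclose(np.diag(K.values), 1.0)
            off = K.off_diagonal()
            assert np.all(off >= -1e-12)
            assert np.all(off <= 1.0 + 1e-10)

    def test_zero_msv_entity_dropped_with_warning(self, worked_example,
                                                  caplog):
        gmap, geno, eff = worked_example
        hap = np.concatenate(
            [geno.haplotypes, np.ones((1, 2, 3), dtype=np.int8)]
        )
        tri = PhasedGenotypes(hap, np.array(["p1", "p2", "hom"]))
        S = build_S(tri, gmap, eff)
        K = standardize(S)
        assert K.entities == ("p1", "p2")

    def test_all_zero_rejected(self, worked_example):
        gmap, _, eff = worked_example
        hom = PhasedGenotypes(
            np.ones((2, 2, 3), dtype=np.int8), np.array(["a", "b"])
        )
        S = build_S(hom, gmap, eff)
        with pytest.raises(ValueError):
            standardize(S)


class TestNearPd:
    def test_psd_input_unchanged(self):
        A = np.array([[2.0, 0.5], [0.5, 1.0]])
        assert near_pd(A) == pytest.approx(A, abs=1e-12)

    def test_known_indefinite_example(self):
        # eigenvalues (3, -1) clip to (3, 0)
        A = np.array([[1.0, 2.0], [2.0, 1.0]])
        assert near_pd(A) == pytest.approx(
            np.array([[1.5, 1.5], [1.5, 1.5]]), abs=1e-10
        )

    def test_random_indefinite_matrices_become_psd(self):
        rng = np.random.default_rng(37)
        for _ in range(10):
            B = rng.normal(size=(20, 20))
            A = 0.5 * (B + B.T)
            out = near_pd(A)
            w = np.linalg.eigvalsh(out)
            assert w.min() >= -1e-8 * max(abs(w.max()), 1.0)
            assert np.allclose(out, out.T)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            near_pd(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestSharedHeterozygosity:
    def test_worked_example_count(self, worked_example):
        _, geno, eff = worked_example
        assert shared_heterozygosity(geno, "p1", "p2") == 3
        assert weighted_shared_effects(
            geno, eff, "p1", "p2"
        ) == pytest.approx(1.0 + 0.04 + 0.0004)

    def test_disjoint_heterozygosity_is_zero(self):
        hap = np.array(
            [[[1, 0], [0, 0]], [[1, 1], [1, 0]]], dtype=np.int8
        )
        geno = PhasedGenotypes(hap, np.array(["a", "b"]))
        eff = MarkerEffects([[2.0, 3.0]], ("t",))
        assert shared_heterozygosity(geno, "a", "b") == 0
        assert weighted_shared_effects(geno, eff, "a", "b") == 0.0

    def test_quarter_weighted_sum_is_unlinked_identity(self):
        # unlinked markers in identical phase: similarity equals the
        # weighted shared-heterozygosity sum over 4
        rng = np.random.default_rng(38)
        n_markers = 6
        gmap = GeneticMap(
            ["1"] * n_markers, np.arange(n_markers) * 60.0,
            [f"m{k}" for k in range(n_markers)],
        )
        het = rng.integers(0, 2, size=(2, n_markers)).astype(bool)
        hap = np.ones((2, 2, n_markers), dtype=np.int8)
        hap[:, 1, :][het] = 0  # heterozygous, reference on hap 1
        geno = PhasedGenotypes(hap, np.array(["a", "b"]))
        eff = MarkerEffects(rng.normal(size=(1, n_markers)), ("t",))
        R = build_R_all(gmap)
        ma = signed_effects(geno, gmap, eff, "a")
        mb = signed_effects(geno, gmap, eff, "b")
        assert pairwise_similarity(ma, mb, R) == pytest.approx(
            weighted_shared_effects(geno, eff, "a", "b") / 4, abs=1e-10
        )
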