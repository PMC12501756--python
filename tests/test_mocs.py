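from itertools import product

import numpy as np
import pytest
from scipy.stats import norm

from msvtools.genome_model import PhasedGenotypes
from msvtools.mocs import (
    ContributionProblem,
    allocate_matings,
    calibrate_constraint,
    inbreeding_constraint,
    selection_index,
    solve_contributions,
    vanraden_grm,
)
from msvtools.similarity import SimilarityMatrix

from .conftest import MSV_PARENT1, MSV_PARENT2, SIMILARITY_12


def random_problem(rng, n=10, q_bar=0.3):
    r = rng.normal(size=n)
    B = rng.normal(size=(n, n))
    Q = B @ B.T / n
    is_male = np.zeros(n, dtype=bool)
    is_male[rng.choice(n, size=n // 2, replace=False)] = True
    return ContributionProblem(r, Q, q_bar=q_bar, is_male=is_male)


def brute_force_objective(problem, steps=8):
    """Best objective over a coarse grid on the two per-sex simplices."""
    n = len(problem.criterion)
    males = np.flatnonzero(problem.is_male)
    females = np.flatnonzero(~problem.is_male)
    best = -np.inf

    def compositions(total, k):
        if k == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, k - 1):
                yield (first,) + rest

    for cm in compositions(steps, len(males)):
        xm = np.array(cm) / steps * 0.5
        for cf in compositions(steps, len(females)):
            xf = np.array(cf) / steps * 0.5
            x = np.zeros(n)
            x[males] = xm
            x[females] = xf
            if 0.5 * x @ problem.Q @ x <= problem.q_bar + 1e-12:
                best = max(best, x @ problem.criterion)
    return best


class TestSelectionIndex:
    def test_median_proportion_gives_breeding_value(self):
        assert selection_index(3.7, 2.0, 0.5) == pytest.approx(3.7)

    def test_one_percent_proportion(self):
        assert selection_index(0.0, 1.0, 0.01) == pytest.approx(
            2 * norm.isf(0.01), abs=1e-6
        )

    def test_zero_msv_gives_breeding_value(self):
        assert selection_index(1.5, 0.0, 0.1) == pytest.approx(1.5)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            selection_index(0.0, -1.0, 0.1)
        with pytest.raises(ValueError):
            selection_index(0.0, 1.0, 1.5)


class TestCalibration:
    @pytest.fixture
    def table_S(self):
        return SimilarityMatrix(
            ("p1", "p2"),
            np.array([[MSV_PARENT1, SIMILARITY_12],
                      [SIMILARITY_12, MSV_PARENT2]]),
            "S", "trait",
        )

    def test_two_by_two_any_percentile(self, table_S):
        # single off-diagonal: every percentile returns it
        for pct in (0, 30, 100):
            scaled, q_bar, scale = calibrate_constraint(table_S, pct)
            assert scale == pytest.approx(MSV_PARENT1)
            assert q_bar == pytest.approx(
                SIMILARITY_12 / MSV_PARENT1, abs=1e-6
            )

    def test_scale_by_max_msv(self, table_S):
        _, _, scale = calibrate_constraint(table_S, 50,
                                           scale_mode="max_msv")
        assert scale == pytest.approx(MSV_PARENT1)

    def test_extreme_percentiles(self):
        rng = np.random.default_rng(0)
        B = rng.uniform(0.1, 1.0, size=(5, 5))
        S = SimilarityMatrix(tuple("abcde"), 0.5 * (B + B.T), "S", "t")
        off = S.off_diagonal() / S.values.max()
        _, lo_bar, _ = calibrate_constraint(S, 0)
        _, hi_bar, _ = calibrate_constraint(S, 100)
        assert lo_bar == pytest.approx(off.min())
        assert hi_bar == pytest.approx(off.max())

    def test_degenerate_matrix_rejected(self):
        S = SimilarityMatrix(("a", "b"), np.zeros((2, 2)), "S", "t")
        with pytest.raises(ValueError):
            calibrate_constraint(S, 50)


class TestSolver:
    def test_unconstrained_concentrates_on_top_candidates(self):
        rng = np.random.default_rng(1)
        prob = random_problem(rng, q_bar=np.inf)
        sol = solve_contributions(prob)
        assert sol.feasible
        males = prob.is_male
        expected = 0.5 * prob.criterion[males].max() + \
            0.5 * prob.criterion[~males].max()
        assert sol.objective == pytest.approx(expected, abs=1e-6)

    def test_symmetric_males_forced_to_split(self):
        # two identical males and one female with a diagonal Q: the
        # quadratic cap set just above the equal-split value forces the
        # 0.25/0.25 division
        v = 2.0
        Q = np.eye(3) * v
        r = np.array([1.0, 1.0, 0.0])
        is_male = np.array([True, True, False])
        equal_quad = 0.5 * v * (0.25**2 + 0.25**2 + 0.5**2)
        prob = ContributionProblem(r, Q, q_bar=equal_quad + 1e-9,
                                   is_male=is_male)
        sol = solve_contributions(prob)
        assert sol.feasible
        assert sol.contributions[:2] == pytest.approx([0.25, 0.25],
                                                      abs=1e-4)

    def test_constraints_hold_on_random_problems(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            prob = random_problem(rng, q_bar=float(rng.uniform(0.1, 0.6)))
            sol = solve_contributions(prob)
            if not sol.feasible:
                continue
            x = sol.contributions
            assert x.min() >= -1e-12
            assert x[prob.is_male].sum() == pytest.approx(0.5, abs=1e-8)
            assert x[~prob.is_male].sum() == pytest.approx(0.5, abs=1e-8)
            assert 0.5 * x @ prob.Q @ x <= prob.q_bar + 1e-8

    def test_matches_brute_force_grid(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            prob = random_problem(rng, n=6, q_bar=0.35)
            sol = solve_contributions(prob)
            assert sol.feasible
            grid = brute_force_objective(prob, steps=8)
            # the continuous optimum dominates any grid point
            assert sol.objective >= grid - 1e-3

    def test_objective_monotone_in_cap(self):
        rng = np.random.default_rng(4)
        prob = random_problem(rng)
        prev = -np.inf
        for q_bar in [0.08, 0.15, 0.3, 0.6, 1.2, np.inf]:
            p = ContributionProblem(prob.criterion, prob.Q, q_bar=q_bar,
                                    is_male=prob.is_male)
            sol = solve_contributions(p)
            if not sol.feasible:
                continue
            assert sol.objective >= prev - 1e-6
            prev = sol.objective

    def test_infeasible_cap_reported(self):
        Q = np.eye(4)
        r = np.ones(4)
        is_male = np.array([True, True, False, False])
        # minimum of n'Qn/2 over the two simplices is 0.0625; cap below it
        prob = ContributionProblem(r, Q, q_bar=0.01, is_male=is_male)
        sol = solve_contributions(prob)
        assert sol.status == "infeasible"
        assert not sol.feasible

    def test_non_psd_without_repair_rejected(self):
        Q = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            solve_contributions(ContributionProblem(
                np.ones(2), Q, q_bar=1.0,
                is_male=np.array([True, False]), repair=False,
            ))

    def test_min_sires_floor(self):
        rng = np.random.default_rng(5)
        n = 12
        r = rng.normal(size=n)
        Q = np.eye(n) * 0.1
        is_male = np.arange(n) < 6
        prob = ContributionProblem(r, Q, q_bar=np.inf, is_male=is_male,
                                   min_sires=4)
        sol = solve_contributions(prob)
        assert sol.feasible
        assert sol.n_selected_males >= 4

    def test_max_sires_tightening(self):
        rng = np.random.default_rng(6)
        n = 12
        r = rng.normal(size=n)
        B = rng.normal(size=(n, n))
        Q = B @ B.T / n
        is_male = np.arange(n) < 6
        prob = ContributionProblem(r, Q, q_bar=0.05, is_male=is_male,
                                   max_sires=2)
        sol = solve_contributions(prob)
        if sol.feasible:
            assert sol.n_selected_males <= 2


class TestGrm:
    def test_heterozygous_at_half_frequency_gives_zero_diagonal(self):
        # dosage 1 everywhere with p = 0.5 centres Z to exactly zero
        hap = np.zeros((2, 2, 4), dtype=np.int8)
        hap[:, 0, :] = 1
        geno = PhasedGenotypes(hap, np.array(["a", "b"]))
        G = vanraden_grm(geno)
        assert G == pytest.approx(np.zeros((2, 2)), abs=1e-12)

    def test_opposite_homozygotes_closed_form(self):
        # individuals fixed for opposite alleles: p = 0.5, Z = +-1 per
        # marker, denominator 2 * m * 0.25 -> diagonal 2, off-diagonal -2
        m = 5
        hap = np.zeros((2, 2, m), dtype=np.int8)
        hap[0] = 1
        geno = PhasedGenotypes(hap, np.array(["a", "b"]))
        G = vanraden_grm(geno)
        assert G == pytest.approx(np.array([[2.0, -2.0], [-2.0, 2.0]]))

    def test_monomorphic_only_rejected(self):
        hap = np.ones((2, 2, 3), dtype=np.int8)
        geno = PhasedGenotypes(hap, np.array(["a", "b"]))
        with pytest.raises(ValueError):
            vanraden_grm(geno)

    def test_centering_row_means(self):
        rng = np.random.default_rng(7)
        hap = rng.integers(0, 2, size=(8, 2, 30)).astype(np.int8)
        geno = PhasedGenotypes(hap, np.array([f"s{k}" for k in range(8)]))
        X = geno.dosage.astype(float)
        p = X.mean(axis=0) / 2
        poly = (p > 0) & (p < 1)
        Z = X[:, poly] - 2 * p[poly]
        assert Z.mean(axis=0) == pytest.approx(
            np.zeros(poly.sum()), abs=1e-12
        )

    def test_inbreeding_constraint_recursion(self):
        G = np.array([[1.0, 0.2], [0.2, 1.0]])
        c_bar = G.mean() / 2
        assert inbreeding_constraint(G, 0.01) == pytest.approx(
            c_bar + 0.01 * (1 - c_bar)
        )


class TestAllocateMatings:
    def test_equal_contributions_split_evenly(self):
        rng = np.random.default_rng(8)
        sol = np.full(5, 0.1)
        matings = allocate_matings(sol, list("ABCDE"),
                                   [f"f{k}" for k in range(250)], rng)
        counts = {m: 0 for m in "ABCDE"}
        females = set()
        for s, f in matings:
            counts[s] += 1
            females.add(f)
        assert all(c == 50 for c in counts.values())
        assert len(females) == 250

    def test_cap_redistributes_excess(self):
        rng = np.random.default_rng(9)
        contrib = np.array([0.3, 0.1, 0.05, 0.03, 0.02])
        matings = allocate_matings(contrib, list("ABCDE"),
                                   [f"f{k}" for k in range(250)], rng,
                                   max_per_male=50, min_males=5)
        counts = {}
        for s, _ in matings:
            counts[s] = counts.get(s, 0) + 1
        assert max(counts.values()) <= 50
        assert len(counts) >= 5
        assert sum(counts.values()) == 250

    def test_seeded_determinism(self):
        contrib = np.array([0.25, 0.15, 0.1])
        a = allocate_matings(contrib, list("ABC"),
                             [f"f{k}" for k in range(20)],
                             np.random.default_rng(42), min_males=3)
        b = allocate_matings(contrib, list("ABC"),
                             [f"f{k}" for k in range(20)],
                             np.random.default_rng(42), min_males=3)
        assert a == b

    def test_unsatisfiable_rules_named(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError, match="male"):
            allocate_matings(np.array([0.5]), ["A"],
                             [f"f{k}" for k in range(10)], rng,
                             min_males=5)
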