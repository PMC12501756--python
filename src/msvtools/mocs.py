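"""Optimal contribution selection under a haplotype-similarity constraint.

The optimiser maximises the expected genetic return of the next generation,
``n' r``, over contribution fractions ``n`` subject to

* a quadratic cap on the average similarity of selected parents,
  ``n' Q n / 2 <= Qbar``, where ``Q`` is a similarity matrix (S or K) or a
  genomic relationship matrix (GRM; this turns the scheme into classical
  OCS with a coancestry constraint — same solver, different matrix);
* sex-sum constraints ``n' v_f = n' v_m = 1/2`` (each sex transmits half the
  genes of the next generation);
* non-negativity and optional per-candidate upper bounds.

This is a convex, linearly objective, quadratically constrained program when
``Q`` is positive semidefinite; indefinite inputs must be repaired first
(see :func:`msvtools.similarity.near_pd`).  It is solved with SLSQP from a
deterministic uniform-within-sex start, and every returned solution is
verified against its constraints — never assumed feasible.

The module also provides the usefulness-style selection index
``I = b + 2 x_p sigma_g`` (breeding value plus twice the standardised
truncation point times the Mendelian standard deviation), constraint
calibration from base-population similarity quantiles, VanRaden Method 1
GRMs, and the conversion of continuous contributions into an integer mating
list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .genome_model import PhasedGenotypes
from .similarity import SimilarityMatrix, near_pd

logger = logging.getLogger(__name__)

__all__ = [
    "ContributionProblem",
    "ContributionSolution",
    "selection_index",
    "calibrate_constraint",
    "solve_contributions",
    "vanraden_grm",
    "allocate_matings",
    "inbreeding_constraint",
]

CONSTRAINT_TOL = 1e-8
SUPPORT_EPS = 1e-6


@dataclass
class ContributionProblem:
    """Inputs of the contribution optimisation.

    ``criterion`` is the per-candidate selection criterion r_t (breeding
    values or indices); ``Q`` the constraint matrix with ``q_kind`` in
    {'S', 'K', 'GRM'}; ``q_bar`` the cap on n'Qn/2; ``is_male`` a boolean
    mask (females are its complement); ``upper_bounds`` optional
    per-candidate caps; ``min_sires``/``max_sires`` bounds on the number of
    males with non-negligible contribution.
    """

    criterion: np.ndarray
    Q: np.ndarray
    q_bar: float
    is_male: np.ndarray
    q_kind: str = "S"
    upper_bounds: np.ndarray | None = None
    min_sires: int | None = None
    max_sires: int | None = None
    repair: bool = True

    def __post_init__(self):
        self.criterion = np.asarray(self.criterion, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.is_male = np.asarray(self.is_male, dtype=bool)
        n = len(self.criterion)
        if self.Q.shape != (n, n):
            raise ValueError("Q must be square over the candidates")
        if self.is_male.shape != (n,):
            raise ValueError("one sex flag per candidate required")
        if self.upper_bounds is not None:
            self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
            if self.upper_bounds.shape != (n,):
                raise ValueError("one upper bound per candidate required")


@dataclass
class ContributionSolution:
    """Optimal contributions and diagnostics."""

    contributions: np.ndarray
    objective: float
    quadratic: float
    status: str
    n_selected_males: int
    n_selected_females: int
    binding: bool = False
    iterations: int = 1
    notes: list = field(default_factory=list)

    @property
    def feasible(self) -> bool:
        return self.status == "optimal"


def selection_index(b, msv, p: float):
    """Usefulness-style index ``I = b + 2 x_p sqrt(msv)``.

    ``x_p`` is the standard-normal truncation point for selected proportion
    ``p`` (upper-tail mass p).  Accepts scalars or arrays.
    """
    if not 0 < p < 1:
        raise ValueError("selected proportion must lie in (0, 1)")
    msv = np.asarray(msv, dtype=float)
    if np.any(msv < 0):
        raise ValueError("MSV must be non-negative")
    x_p = norm.isf(p)
    out = np.asarray(b, dtype=float) + 2.0 * x_p * np.sqrt(msv)
    return float(out) if out.ndim == 0 else out


def calibrate_constraint(S_base: SimilarityMatrix, percentile: float,
                         scale_mode: str = "max"):
    """Scale a base-population similarity matrix and pick the constraint cap.

    The matrix is divided by its maximum element (``scale_mode='max'``) or
    its maximum diagonal MSV (``'max_msv'``) so one cap stays meaningful
    across generations; the cap ``Qbar`` is the requested percentile of the
    scaled off-diagonal similarity distribution.  Returns
    ``(scaled_matrix, q_bar, scale)``; apply the same ``scale`` to later
    generations' matrices.
    """
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must lie in [0, 100]")
    V = S_base.values
    if scale_mode == "max":
        scale = float(np.max(V))
    elif scale_mode == "max_msv":
        scale = float(np.max(np.diag(V)))
    else:
        raise ValueError("scale_mode must be 'max' or 'max_msv'")
    if scale <= 0:
        raise ValueError("degenerate all-zero similarity matrix")
    scaled = V / scale
    off = scaled[np.triu_indices(V.shape[0], k=1)]
    if off.size == 0:
        raise ValueError("need at least two entities to calibrate")
    q_bar = float(np.percentile(off, percentile))
    return scaled, q_bar, scale


def _solve_qcqp(r, Q, q_bar, is_male, ub, lb=None, x_init=None):
    """Solve: max n'r s.t. n'Qn/2 <= q_bar, sex sums = 1/2,
    lb <= n <= ub (lb defaults to 0; used for min-sire floors).

    A sex whose bounds leave no slack (its upper bounds sum to exactly the
    sex target, or its lower bounds do) is eliminated before the numerical
    solve: its coordinates are fixed and fold into a linear term of the
    quadratic constraint.  In the breeding-program setting this removes the
    entire female block (females are pinned at uniform contributions),
    halving the problem and sparing the solver a wall of active bounds.
    """
    n = len(r)
    lo = np.zeros(n) if lb is None else np.asarray(lb, dtype=float)
    hi = np.full(n, np.inf) if ub is None else np.maximum(ub, lo)
    fixed = np.zeros(n, dtype=bool)
    x_fix = np.zeros(n)
    groups = []
    for mask in (~is_male, is_male):
        if not mask.any():
            continue
        if hi[mask].sum() <= 0.5 + 1e-12:
            if hi[mask].sum() < 0.5 - CONSTRAINT_TOL:
                return None, "infeasible"  # sex cannot reach its half
            fixed[mask] = True
            x_fix[mask] = hi[mask]
        elif lo[mask].sum() >= 0.5 - 1e-12:
            if lo[mask].sum() > 0.5 + CONSTRAINT_TOL:
                return None, "infeasible"
            fixed[mask] = True
            x_fix[mask] = lo[mask]
        else:
            groups.append(mask)

    if not fixed.any():
        return _solve_core(
            r, Q, np.zeros(n), 0.0, q_bar, groups, lo, hi,
            None if x_init is None else np.asarray(x_init, dtype=float),
        )

    free = ~fixed
    if not free.any():
        quad = 0.5 * x_fix @ Q @ x_fix
        ok = not np.isfinite(q_bar) or quad <= q_bar + CONSTRAINT_TOL
        return (x_fix, "optimal") if ok else (None, "infeasible")
    b_lin = Q[np.ix_(free, fixed)] @ x_fix[fixed]
    c0 = 0.5 * x_fix @ Q @ x_fix
    xf, status = _solve_core(
        r[free], Q[np.ix_(free, free)], b_lin, c0, q_bar,
        [g[free] for g in groups], lo[free], hi[free],
        None if x_init is None else np.asarray(x_init, dtype=float)[free],
    )
    if xf is None:
        return None, status
    x = x_fix.copy()
    x[free] = xf
    return x, status


def _solve_core(r, Q, b, c, q_bar, groups, lo, hi, x_init):
    """Numerical core: max x'r s.t. 0.5 x'Qx + b'x + c <= q_bar, per-group
    sums = 1/2, lo <= x <= hi.

    SLSQP from a deterministic start, with polishing of the group sums, a
    restart-and-restore pass for line-search stalls, an explicit KKT
    certificate, and a trust-region fallback.  The returned status is
    'optimal' only for a point that passes the feasibility check and is
    certified (solver convergence or KKT).
    """
    n = len(r)

    def quad(v):
        return 0.5 * v @ Q @ v + b @ v + c

    def quad_grad(v):
        return Q @ v + b

    def _polished(v):
        v = np.clip(v, lo, hi)
        for g in groups:
            s = v[g].sum()
            if s > 0:
                v = v.copy()
                v[g] *= 0.5 / s
        return np.clip(v, lo, hi)

    def _quad_viol(v):
        return (quad(v) - q_bar) if np.isfinite(q_bar) else -np.inf

    def _verify(v):
        # feasibility is checked explicitly, never assumed
        return (
            all(abs(v[g].sum() - 0.5) <= CONSTRAINT_TOL for g in groups)
            and _quad_viol(v) <= CONSTRAINT_TOL
            and np.all(v <= hi + CONSTRAINT_TOL)
            and np.all(v >= lo - CONSTRAINT_TOL)
        )

    def _certified(v, converged):
        return _verify(v) and (
            converged
            or _kkt_optimal(v, r, quad_grad(v), q_bar - c, quad(v) - c,
                            groups, lo, hi)
        )

    # single-sum problems (the common case once one sex is eliminated) go
    # through a fast active-set solve with a closed-form Lagrangian core;
    # the generic SLSQP/trust-region path below is the fallback
    if len(groups) == 1 and groups[0].all():
        x_as = _active_set_qcqp(r, Q, b, c, q_bar, 0.5, lo, hi)
        if x_as is not None and _certified(x_as, False):
            return _polished(x_as), "optimal"

    if x_init is not None:
        x0 = np.clip(x_init, lo, hi)
    else:
        x0 = np.zeros(n)
        for g in groups:
            x0[g] = 0.5 / g.sum()
        x0 = _polished(x0)
    cons = [
        {"type": "eq",
         "fun": (lambda x, gg=g.astype(float): x @ gg - 0.5),
         "jac": (lambda x, gg=g.astype(float): gg)}
        for g in groups
    ]
    cons_eq = list(cons)
    bounds = list(zip(lo, hi))
    if np.isfinite(q_bar):
        cons.append({
            "type": "ineq",
            "fun": lambda x: q_bar - quad(x),
            "jac": lambda x: -quad_grad(x),
        })
        if quad(x0) > q_bar:
            # find a feasible start: minimise the quadratic over the simplex
            res0 = minimize(
                quad, x0, jac=quad_grad,
                method="SLSQP", constraints=cons_eq, bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-12},
            )
            if res0.fun > q_bar + CONSTRAINT_TOL:
                return None, "infeasible"
            x0 = np.clip(res0.x, lo, hi)
    x_start = x0.copy()

    res = minimize(
        lambda x: -(x @ r), x0, jac=lambda x: -r, method="SLSQP",
        constraints=cons, bounds=bounds,
        options={"maxiter": 1000, "ftol": 1e-12},
    )
    x = _polished(res.x)
    if _quad_viol(x) > CONSTRAINT_TOL:
        # SLSQP line-search stalls can leave a tiny constraint violation;
        # restart once from the stalled point, then restore feasibility
        # along the segment back to the strictly feasible start
        res = minimize(
            lambda v: -(v @ r), x, jac=lambda v: -r,
            method="SLSQP", constraints=cons, bounds=bounds,
            options={"maxiter": 1000, "ftol": 1e-12},
        )
        x = _polished(res.x)
        if _quad_viol(x) > CONSTRAINT_TOL and _quad_viol(x_start) < 0:
            x = _restore_quadratic(x_start, x, Q, b, c, q_bar)
    if _certified(x, res.success):
        return x, "optimal"
    # fall back to the more robust (if slower) trust-region solver
    x2 = _solve_trust_constr(r, Q, b, c, q_bar, groups, lo, hi, x_start)
    if x2 is not None:
        x2 = _polished(x2)
        if _quad_viol(x2) > CONSTRAINT_TOL and _quad_viol(x_start) < 0:
            x2 = _restore_quadratic(x_start, x2, Q, b, c, q_bar)
        if _certified(x2, False):
            return x2, "optimal"
        if _verify(x2) and (not _verify(x) or x2 @ r >= x @ r):
            return x2, "failed"
    return x, "failed"


def _greedy_fill(r, lo, hi, target):
    """Linear-program optimum for max r'x, sum x = target, lo <= x <= hi:
    start everyone at the floor, pour the remaining mass into the best
    candidates up to their caps (fractional knapsack)."""
    x = lo.copy()
    rest = target - x.sum()
    if rest < -CONSTRAINT_TOL:
        return None
    for i in np.lexsort((np.arange(len(r)), -r)):
        room = hi[i] - x[i]
        take = min(room, rest)
        x[i] += take
        rest -= take
        if rest <= 0:
            break
    return x if rest <= CONSTRAINT_TOL else None


def _active_set_qcqp(r, Q, b, c, q_bar, target, lo, hi,
                     max_iter: int = 200):
    """Active-set solve of max r'x s.t. 0.5 x'Qx + b'x + c <= q_bar,
    sum x = target, lo <= x <= hi.

    If the quadratic cap is slack at the linear-program optimum, that
    optimum is returned.  Otherwise the cap is treated as an equality and,
    for a working set of free coordinates, the stationarity system is
    solved in closed form: with A = Q_SS^-1 the free block is
    x_S(t) = t v1 + v2 where t = 1/mu is fixed by the cap (a scalar
    quadratic), v1 the projected gain direction and v2 the minimum-
    similarity point.  Coordinates violating their bounds are clamped and
    the system re-solved; clamped coordinates whose reduced cost has the
    wrong sign are released one at a time.  Returns None when the linear
    algebra degenerates — the caller falls back to iterative solvers.
    """

    def quad(v):
        return 0.5 * v @ Q @ v + b @ v + c

    x_lp = _greedy_fill(r, lo, hi, target)
    if x_lp is None:
        return None
    if not np.isfinite(q_bar) or quad(x_lp) <= q_bar:
        return x_lp

    n = len(r)
    at_lo = np.zeros(n, dtype=bool)
    at_hi = np.zeros(n, dtype=bool)
    x = None
    for _ in range(max_iter):
        S = ~at_lo & ~at_hi
        if not S.any():
            return None
        x_fix = np.where(at_hi, hi, np.where(at_lo, lo, 0.0))
        s = target - x_fix.sum()
        q_S = b[S] + Q[np.ix_(S, ~S)] @ x_fix[~S]
        Q_SS = Q[np.ix_(S, S)]
        try:
            sols = np.linalg.solve(
                Q_SS + 1e-12 * np.eye(S.sum()),
                np.column_stack([r[S], np.ones(S.sum()), q_S]),
            )
        except np.linalg.LinAlgError:
            return None
        u1, u2, u3 = sols.T
        d = u2.sum()
        if not np.isfinite(d) or abs(d) < 1e-14:
            return None
        v1 = u1 - (u1.sum() / d) * u2
        v2 = -u3 + ((s + u3.sum()) / d) * u2

        def assemble(t):
            v = x_fix.copy()
            v[S] = t * v1 + v2
            return v

        f0, f1, fm1 = quad(assemble(0)), quad(assemble(1)), quad(
            assemble(-1))
        gamma = f0
        alpha = 0.5 * (f1 + fm1) - gamma
        beta = 0.5 * (f1 - fm1)
        disc = beta * beta - 4.0 * alpha * (gamma - q_bar)
        if alpha <= 1e-18:
            return None
        if disc < 0:
            return None  # cap unreachable on this face
        t = (-beta + np.sqrt(disc)) / (2.0 * alpha)
        if t <= 0:
            return None
        x = assemble(t)
        mu = 1.0 / t
        lam = (u1.sum() - mu * (s + u3.sum())) / d

        # clamp bound violators (all at once), then try releases
        viol_lo = S & (x < lo - CONSTRAINT_TOL)
        viol_hi = S & (x > hi + CONSTRAINT_TOL)
        if viol_lo.any() or viol_hi.any():
            at_lo |= viol_lo
            at_hi |= viol_hi
            continue
        g = Q @ x + b
        rc = r - mu * g - lam
        scale = max(np.abs(r).max(), 1.0)
        release_lo = at_lo & (rc > 1e-9 * scale)
        release_hi = at_hi & (rc < -1e-9 * scale)
        if not release_lo.any() and not release_hi.any():
            return np.clip(x, lo, hi)
        # release the single worst offender to avoid cycling
        cand = np.where(release_lo, rc, 0.0) - np.where(release_hi, rc, 0.0)
        worst = int(np.argmax(cand))
        at_lo[worst] = False
        at_hi[worst] = False
    return None


def _solve_trust_constr(r, Q, b, c, q_bar, groups, lo, hi, x0):
    """Trust-region solve of the same program; returns the raw iterate."""
    from scipy.optimize import (
        Bounds,
        LinearConstraint,
        NonlinearConstraint,
    )

    n = len(r)
    constraints = []
    if groups:
        rows = np.array([g.astype(float) for g in groups])
        rhs = np.full(len(groups), 0.5)
        constraints.append(LinearConstraint(rows, rhs, rhs))
    if np.isfinite(q_bar):
        constraints.append(NonlinearConstraint(
            lambda x: 0.5 * x @ Q @ x + b @ x + c, -np.inf, q_bar,
            jac=lambda x: Q @ x + b, hess=lambda x, v: v[0] * Q,
        ))
    zero_hess = np.zeros((n, n))
    try:
        res = minimize(
            lambda x: -(x @ r), x0, jac=lambda x: -r,
            method="trust-constr",
            constraints=constraints,
            bounds=Bounds(lo, np.where(np.isinf(hi), 1.0, hi)),
            hess=lambda x: zero_hess,
            options={"maxiter": 500, "gtol": 1e-10, "xtol": 1e-12},
        )
    except Exception:
        return None
    return res.x


def _kkt_optimal(x, r, quad_grad_x, q_cap, q_val, groups, lo, hi,
                 tol: float = 1e-5) -> bool:
    """First-order optimality check for the contribution QCQP.

    Estimates the multipliers of the active constraints by least squares on
    the free coordinates and verifies stationarity, dual feasibility of the
    quadratic multiplier, and the sign conditions at active bounds.  Used to
    certify solutions when SLSQP stalls in its line search at an optimum.
    ``quad_grad_x`` is the gradient of the quadratic at ``x``; ``q_val`` and
    ``q_cap`` its value and cap (both net of any constant term).
    """
    scale = max(np.abs(r).max(), 1.0)
    active_lower = x <= lo + SUPPORT_EPS
    active_upper = x >= hi - SUPPORT_EPS
    free = ~active_lower & ~active_upper
    quad_active = np.isfinite(q_cap) and (
        q_val >= q_cap - 1e-6 * max(abs(q_cap), 1.0)
    )
    # multipliers identifiable from free coordinates (stationarity there
    # is an equality); groups with every coordinate at a bound get their
    # multiplier from interval feasibility instead
    cols = [g.astype(float) for g in groups if (g & free).any()]
    if quad_active:
        cols.append(quad_grad_x)
    if cols:
        A = np.column_stack(cols)
        mult, *_ = np.linalg.lstsq(A[free], r[free], rcond=None)
        if quad_active and mult[-1] < -tol * scale:
            return False  # quadratic multiplier must be non-negative
        t = r - A @ mult
    else:
        if quad_active:
            return False  # cannot identify the quadratic multiplier
        t = r.copy()
    if free.any() and np.abs(t[free]).max() > tol * scale:
        return False
    # coordinates pinned between coinciding bounds carry no sign condition
    only_lower = active_lower & ~active_upper
    only_upper = active_upper & ~active_lower
    for g in groups:
        if (g & free).any():
            # multiplier already fitted: sign conditions at the bounds
            if np.any(t[g & only_lower] > tol * scale):
                return False
            if np.any(t[g & only_upper] < -tol * scale):
                return False
        else:
            # choose the group multiplier freely: it must dominate every
            # lower-active reduced cost and stay below every upper-active
            lo_t = t[g & only_lower]
            up_t = t[g & only_upper]
            lo_max = lo_t.max() if lo_t.size else -np.inf
            up_min = up_t.min() if up_t.size else np.inf
            if lo_max > up_min + 2 * tol * scale:
                return False
    # coordinates outside every group (none in practice): reduced cost signs
    in_group = np.zeros(len(x), dtype=bool)
    for g in groups:
        in_group |= g
    rest = ~in_group
    if np.any(t[rest & only_lower] > tol * scale):
        return False
    if np.any(t[rest & only_upper] < -tol * scale):
        return False
    return True


def _restore_quadratic(x_feas, x, Q, b, c, q_bar):
    """Largest convex combination of a strictly feasible point and an
    infeasible iterate that satisfies the quadratic cap.

    Both endpoints satisfy the linear constraints and bounds, so every
    point on the segment does too; the quadratic along the segment is a
    scalar quadratic in t whose root is taken in closed form (with a tiny
    inward margin against roundoff).
    """
    d = x - x_feas
    aa = 0.5 * d @ Q @ d
    bb = x_feas @ Q @ d + b @ d
    cc = 0.5 * x_feas @ Q @ x_feas + b @ x_feas + c - q_bar
    disc = bb * bb - 4.0 * aa * cc
    if aa <= 0 or disc < 0:
        return x_feas
    t = (-bb + np.sqrt(disc)) / (2.0 * aa)
    t = min(max(t, 0.0), 1.0) * (1.0 - 1e-10)
    return x_feas + t * d


def solve_contributions(problem: ContributionProblem) -> ContributionSolution:
    """Solve the contribution QCQP, with iterative sire-count adaptation.

    The continuous program cannot express a cardinality constraint directly;
    when the male support exceeds ``max_sires`` the per-candidate upper
    bounds of the weakest supported males are tightened to zero and the
    program re-solved (up to 50 rounds); when the support falls short of
    ``min_sires`` the best unsupported males receive a small floor
    contribution and the remainder is re-optimised.
    """
    r, is_male = problem.criterion, problem.is_male
    Q = problem.Q
    if problem.repair:
        Q = near_pd(Q)
    elif np.linalg.eigvalsh(0.5 * (Q + Q.T)).min() < -1e-8:
        raise ValueError("Q is not PSD and repair is disabled")
    ub = (None if problem.upper_bounds is None
          else problem.upper_bounds.copy())
    notes = []
    x, status = _solve_qcqp(r, Q, problem.q_bar, is_male, ub)
    iterations = 1

    if status == "optimal" and problem.max_sires is not None:
        for _ in range(50):
            support = np.flatnonzero(is_male & (x > SUPPORT_EPS))
            if len(support) <= problem.max_sires:
                break
            drop = support[np.argsort(x[support])][
                : len(support) - problem.max_sires
            ]
            if ub is None:
                ub = np.full(len(r), np.inf)
            ub[drop] = 0.0
            x, status = _solve_qcqp(r, Q, problem.q_bar, is_male, ub)
            iterations += 1
            if status != "optimal":
                break
        else:
            notes.append("max_sires adaptation hit iteration cap")

    if status == "optimal" and problem.min_sires is not None:
        support = np.flatnonzero(is_male & (x > SUPPORT_EPS))
        if len(support) < problem.min_sires:
            floor = 1.0 / (2.0 * len(r))
            unsupported = np.flatnonzero(is_male & (x <= SUPPORT_EPS))
            order = unsupported[np.argsort(-r[unsupported])]
            need = problem.min_sires - len(support)
            if len(order) < need:
                raise ValueError(
                    "min_sires unsatisfiable: not enough male candidates"
                )
            chosen = order[:need]
            lb = np.zeros(len(r))
            lb[chosen] = floor
            lb[support] = floor
            # warm start: base optimum lifted to the floors, the freed
            # mass taken from the supported males proportionally
            x_ws = x.copy()
            x_ws[chosen] = floor
            excess = x_ws[is_male].sum() - 0.5
            if excess > 0 and x_ws[support].sum() > 0:
                x_ws[support] -= excess * x_ws[support] / x_ws[support].sum()
                x_ws[support] = np.maximum(x_ws[support], floor)
            x, status = _solve_qcqp(r, Q, problem.q_bar, is_male, ub,
                                    lb=lb, x_init=x_ws)
            iterations += 1
            notes.append(f"min_sires floor applied to {need} males")

    if x is None:
        return ContributionSolution(
            np.zeros(len(r)), np.nan, np.nan, "infeasible", 0, 0,
            iterations=iterations, notes=notes,
        )
    quad = float(0.5 * x @ Q @ x)
    binding = (np.isfinite(problem.q_bar)
               and quad >= problem.q_bar - 1e-6)
    return ContributionSolution(
        x, float(x @ r), quad, status,
        int(np.count_nonzero(is_male & (x > SUPPORT_EPS))),
        int(np.count_nonzero(~is_male & (x > SUPPORT_EPS))),
        binding=binding, iterations=iterations, notes=notes,
    )


def vanraden_grm(genotypes: PhasedGenotypes) -> np.ndarray:
    """Genomic relationship matrix, VanRaden Method 1.

    ``G = Z Z' / (2 sum_k p_k (1 - p_k))`` with ``Z`` the allele-dosage
    matrix centred by twice the sample allele frequency.  Monomorphic
    markers contribute nothing; an input with only monomorphic markers is
    rejected.
    """
    X = genotypes.dosage.astype(float)  # (n, markers), reference dosage
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not np.any(poly):
        raise ValueError("all markers are monomorphic; GRM undefined")
    Z = X[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return (Z @ Z.T) / denom


def inbreeding_constraint(G: np.ndarray, delta_f: float,
                          mean_coancestry: float | None = None) -> float:
    """Per-generation coancestry cap for OCS from a target inbreeding rate.

    Standard OCS recursion: ``Qbar_t = Cbar_{t-1} + dF (1 - Cbar_{t-1})``
    with ``Cbar`` the population mean coancestry (mean of G / 2).
    """
    if mean_coancestry is None:
        mean_coancestry = float(np.mean(G) / 2.0)
    return mean_coancestry + delta_f * (1.0 - mean_coancestry)


def allocate_matings(solution: ContributionSolution, male_ids, female_ids,
                     rng, max_per_male: int = 50, min_males: int = 5):
    """Turn male contributions into a random mating list.

    Each female receives exactly one mating.  Per-male mating counts are the
    contributions times twice the number of females, rounded by the
    largest-remainder method, then capped at ``max_per_male`` with the
    excess redistributed; at least ``min_males`` distinct males must end up
    with matings.  The male identifier vector is shuffled with ``rng`` and
    zipped against the females.
    """
    male_ids = list(male_ids)
    female_ids = list(female_ids)
    n_f = len(female_ids)
    contrib = np.asarray(
        getattr(solution, "contributions", solution), dtype=float
    )
    if len(contrib) != len(male_ids):
        raise ValueError("one contribution per male required")
    counts = _largest_remainder(contrib, n_f)
    # enforce the per-male cap, redistributing to the next-best males
    for _ in range(len(male_ids)):
        over = counts > max_per_male
        if not np.any(over):
            break
        excess = int(np.sum(counts[over] - max_per_male))
        counts[over] = max_per_male
        room = np.flatnonzero((counts < max_per_male) & (counts > 0))
        if room.size == 0:
            room = np.flatnonzero(counts < max_per_male)
        if room.size == 0:
            raise ValueError(
                "mating rules unsatisfiable: per-male cap leaves "
                f"{excess} females unmated"
            )
        order = room[np.argsort(-contrib[room])]
        for k in order:
            take = min(excess, max_per_male - counts[k])
            counts[k] += take
            excess -= take
            if excess == 0:
                break
    if np.count_nonzero(counts) < min_males:
        # give one mating each to the best males without one
        zero = np.flatnonzero(counts == 0)
        order = zero[np.argsort(-contrib[zero])]
        need = min_males - np.count_nonzero(counts)
        if len(order) < need:
            raise ValueError(
                "mating rules unsatisfiable: fewer than "
                f"{min_males} male candidates available"
            )
        donors = np.argsort(-counts)
        for k in order[:need]:
            d = donors[0] if counts[donors[0]] > 1 else donors[1]
            counts[d] -= 1
            counts[k] += 1
            donors = np.argsort(-counts)
    assert counts.sum() == n_f
    sire_vector = np.repeat(np.arange(len(male_ids)), counts)
    rng.shuffle(sire_vector)
    return [(male_ids[s], female_ids[f]) for f, s in enumerate(sire_vector)]


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative weights to integers summing to ``total``."""
    w = np.clip(weights, 0.0, None)
    if w.sum() == 0:
        raise ValueError("all contributions are zero")
    quota = w / w.sum() * total
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    return base
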