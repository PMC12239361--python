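"""Optimization models against independent brute-force oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from dietopt.constraints import ConstraintSet, LinearConstraint
from dietopt.food_model import DietVector
from dietopt.optimizer import (
    OptimizationProblem,
    SolverOptions,
    inward_grid_bracket,
    make_grid,
    meat_cap_sensitivity,
    multistart_solve,
    solve_ghge_extremum,
    solve_total_departure,
    total_departure,
    total_meat_constraint,
)

from conftest import toy_db, toy_stats


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def enumerate_vertices(cs: ConstraintSet) -> np.ndarray:
    """All basic feasible solutions of {A_ub x <= b_ub, A_eq x = b_eq, x >= 0}.

    Brute force: solve every n x n subsystem of tight rows (constraint rows
    plus coordinate hyperplanes) and keep the feasible solutions.
    """
    n = 2 * cs.n_groups
    rows, rhs = [], []
    for con in cs:
        rows.append(con.coeffs)
        rhs.append(con.rhs)
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        rows.append(e)
        rhs.append(0.0)
    rows = np.array(rows)
    rhs = np.array(rhs)
    vertices = []
    for idx in combinations(range(len(rows)), n):
        A = rows[list(idx)]
        if abs(np.linalg.det(A)) < 1e-10:
            continue
        x = np.linalg.solve(A, rhs[list(idx)])
        if np.any(x < -1e-8):
            continue
        feasible = True
        for con in cs:
            if con.residual(x) > 1e-8 * max(1.0, abs(con.rhs)):
                feasible = False
                break
        if feasible:
            vertices.append(x)
    return np.array(vertices)


def grid_search_td(stats, caps, floor, coarse=120):
    """Two-stage dense grid search for the departure minimum over totals.

    Constraints: per-group total <= cap, sum of totals >= floor.  Works on
    mode-summed totals, which fully determine the departure objective.
    """
    g = len(caps)

    def objective(points):
        dev = (points - stats.mean) / stats.sd
        return np.sum(dev**2, axis=-1)

    def best_on(axes):
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=-1)
        ok = pts.sum(axis=1) >= floor - 1e-9
        pts = pts[ok]
        vals = objective(pts)
        k = int(np.argmin(vals))
        return pts[k], float(vals[k])

    axes = [np.linspace(0, caps[i], coarse + 1) for i in range(g)]
    best, _ = best_on(axes)
    width = np.array([caps[i] / coarse for i in range(g)])
    axes = [
        np.linspace(max(0, best[i] - 2 * width[i]),
                    min(caps[i], best[i] + 2 * width[i]), 161)
        for i in range(g)
    ]
    return best_on(axes)


def random_instance(rng, g):
    """A small random instance with per-group caps and a total-mass floor."""
    mean = rng.uniform(50, 200, g)
    sd = rng.uniform(5, 40, g)
    caps = mean * rng.uniform(1.2, 2.0, g)
    floor = 0.6 * float(mean.sum())
    db = toy_db(rng.uniform(1, 10, g), ghge_org=rng.uniform(1, 10, g))
    stats = toy_stats(mean, sd, p99=caps)
    cons = []
    for i in range(g):
        coeffs = np.zeros(2 * g)
        coeffs[i] = coeffs[g + i] = 1.0
        cons.append(LinearConstraint(coeffs, "<=", float(caps[i]),
                                     "acceptability", f"cap_{i}"))
    cons.append(LinearConstraint(np.ones(2 * g), ">=", floor, "fbdg", "mass_floor"))
    return db, stats, ConstraintSet(cons, g), caps, floor


# ---------------------------------------------------------------------------
# Departure objective
# ---------------------------------------------------------------------------

class TestTotalDeparture:
    def test_zero_at_observed_means(self):
        stats = toy_stats([100.0, 50.0], [20.0, 10.0])
        assert total_departure(DietVector.from_totals([100.0, 50.0]), stats) == 0.0

    def test_hand_value(self):
        # Opt (140, 40) vs Obs (100, 50) with SD (20, 10): 2^2 + 1^2 = 5
        stats = toy_stats([100.0, 50.0], [20.0, 10.0])
        assert total_departure(DietVector.from_totals([140.0, 40.0]), stats) == \
            pytest.approx(5.0)

    def test_homogeneity_in_sd(self):
        rng = np.random.default_rng(4)
        mean, sd = rng.uniform(50, 150, 4), rng.uniform(5, 20, 4)
        diet = DietVector.from_totals(rng.uniform(0, 200, 4))
        td1 = total_departure(diet, toy_stats(mean, sd))
        td2 = total_departure(diet, toy_stats(mean, 2 * sd))
        assert td2 == pytest.approx(td1 / 4)

    def test_zero_sd_groups_are_excluded(self):
        stats = toy_stats([100.0, 50.0], [20.0, 0.0])
        diet = DietVector.from_totals([100.0, 999.0])
        assert total_departure(diet, stats) == 0.0


# ---------------------------------------------------------------------------
# Solver vs oracles
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    @pytest.mark.parametrize("g, seed", [(2, s) for s in range(4)] + [(3, s) for s in range(2)])
    def test_departure_minimum_matches_grid_search(self, g, seed):
        rng = np.random.default_rng(100 + seed)
        db, stats, cs, caps, floor = random_instance(rng, g)
        sol = solve_total_departure(OptimizationProblem(db, stats, cs))
        assert sol.ok
        _, oracle_val = grid_search_td(stats, caps, floor)
        assert sol.td == pytest.approx(oracle_val, abs=1e-3)

    @pytest.mark.parametrize("g, seed", [(2, s) for s in range(3)] + [(3, s) for s in range(2)])
    def test_emission_extrema_match_vertex_enumeration(self, g, seed):
        rng = np.random.default_rng(200 + seed)
        db, stats, cs, *_ = random_instance(rng, g)
        problem = OptimizationProblem(db, stats, cs)
        ghge = np.concatenate([db.ghge[:, 0], db.ghge[:, 1]]) / 1000.0
        vertices = enumerate_vertices(cs)
        assert len(vertices) > 0
        values = vertices @ ghge
        lo = solve_ghge_extremum(problem, "min")
        hi = solve_ghge_extremum(problem, "max")
        assert lo.objective_value == pytest.approx(values.min(), abs=1e-3)
        assert hi.objective_value == pytest.approx(values.max(), abs=1e-3)
        assert lo.objective_value <= hi.objective_value


class TestSolveContracts:
    def test_feasible_observed_mean_is_recovered(self):
        # the observed mean diet satisfies all constraints -> TD = 0 there
        rng = np.random.default_rng(7)
        db, stats, cs, *_ = random_instance(rng, 3)
        sol = solve_total_departure(OptimizationProblem(db, stats, cs))
        assert sol.ok
        assert sol.td == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sol.diet.total, stats.mean, atol=1e-5)

    def test_residuals_within_tolerance(self, scenario):
        problem = OptimizationProblem(scenario.db, scenario.stats, scenario.constraints)
        sol = solve_total_departure(problem)
        assert sol.ok
        assert scenario.constraints.violated(sol.diet.stacked(), tol=1e-6) == []

    def test_stored_td_matches_recomputation(self, scenario):
        problem = OptimizationProblem(scenario.db, scenario.stats, scenario.constraints)
        sol = solve_total_departure(problem)
        recomputed = total_departure(sol.diet, scenario.stats)
        assert sol.td == pytest.approx(recomputed, rel=1e-8)

    def test_single_point_feasible_set_collapses_extrema(self):
        db = toy_db([2.0, 5.0])
        stats = toy_stats([50.0, 50.0], [5.0, 5.0])
        cons = []
        for i in range(2):
            coeffs = np.zeros(4)
            coeffs[i] = coeffs[2 + i] = 1.0
            cons.append(LinearConstraint(coeffs, "==", 100.0, "fbdg", f"fix_{i}"))
        # organic = conventional footprint here, so the point is unique in value
        cs = ConstraintSet(cons, 2)
        problem = OptimizationProblem(db, stats, cs)
        lo = solve_ghge_extremum(problem, "min")
        hi = solve_ghge_extremum(problem, "max")
        assert lo.objective_value == pytest.approx(hi.objective_value, abs=1e-9)

    def test_unbounded_maximum_is_detected(self):
        db = toy_db([2.0, 5.0])
        stats = toy_stats([50.0, 50.0], [5.0, 5.0])
        coeffs = np.zeros(4)
        coeffs[0] = coeffs[2] = 1.0
        cs = ConstraintSet([LinearConstraint(coeffs, "<=", 100.0, "acceptability",
                                             "cap_0")], 2)
        sol = solve_ghge_extremum(OptimizationProblem(db, stats, cs), "max")
        assert sol.status == "error"
        assert "unbounded" in sol.message

    def test_infeasible_reports_conflicting_provenances(self):
        db = toy_db([2.0])
        stats = toy_stats([50.0], [5.0])
        coeffs = np.array([1.0, 1.0])
        cs = ConstraintSet([
            LinearConstraint(coeffs, ">=", 100.0, "fbdg", "floor"),
            LinearConstraint(coeffs, "<=", 50.0, "acceptability", "cap"),
        ], 1)
        sol = solve_total_departure(OptimizationProblem(db, stats, cs))
        assert sol.status == "infeasible"
        assert sol.infeasible_provenances  # at least one named conflict


class TestGrid:
    def test_main_bracket_has_29_levels(self):
        grid = make_grid(1.2, 6.8, 0.2)
        assert len(grid) == 29
        assert grid[0] == pytest.approx(1.2) and grid[-1] == pytest.approx(6.8)
        assert np.allclose(np.diff(grid), 0.2)

    def test_inward_rounding(self):
        lo, hi = inward_grid_bracket(1.16, 6.99, 0.2)
        assert lo == pytest.approx(1.2) and hi == pytest.approx(6.8)
        # already on-grid endpoints stay put
        lo, hi = inward_grid_bracket(1.2, 6.8, 0.2)
        assert lo == pytest.approx(1.2) and hi == pytest.approx(6.8)

    def test_degenerate_bracket(self):
        assert len(make_grid(2.0, 2.0, 0.2)) == 1


class TestMeatCap:
    def test_zero_cap_forces_meat_free_diet(self, scenario):
        problem = OptimizationProblem(scenario.db, scenario.stats, scenario.constraints)
        sols = meat_cap_sensitivity(problem, caps=[0.0])
        sol = sols[0.0]
        assert sol.ok
        mask = (scenario.db.tag_mask("is_red_meat")
                | scenario.db.tag_mask("is_poultry")
                | scenario.db.tag_mask("is_processed_meat"))
        assert sol.diet.total[mask].sum() == pytest.approx(0.0, abs=1e-6)

    def test_binding_cap_shifts_maximum_linearly(self):
        # one meat group holds the top emission coefficient; while its cap
        # binds, the maximum drops by (delta cap / 7) x coefficient
        db = toy_db([20.0, 1.0], tags={0: ("is_red_meat",)})
        stats = toy_stats([50.0, 50.0], [5.0, 5.0])
        g = 2
        cons = []
        for i in range(g):
            coeffs = np.zeros(2 * g)
            coeffs[i] = coeffs[g + i] = 1.0
            cons.append(LinearConstraint(coeffs, "<=", 400.0, "acceptability",
                                         f"cap_{i}"))
        cs = ConstraintSet(cons, g)
        problem = OptimizationProblem(db, stats, cs)
        sols = meat_cap_sensitivity(problem, caps=[700.0, 350.0])
        drop = sols[700.0].objective_value - sols[350.0].objective_value
        assert drop == pytest.approx((350.0 / 7.0) * 20.0 / 1000.0, rel=1e-6)

    def test_maximum_never_increases_as_cap_tightens(self, scenario):
        problem = OptimizationProblem(scenario.db, scenario.stats, scenario.constraints)
        sols = meat_cap_sensitivity(problem, caps=[500.0, 300.0])
        assert sols[300.0].objective_value <= sols[500.0].objective_value + 1e-9


class TestMultistart:
    def test_single_start_equals_plain_solve(self):
        rng = np.random.default_rng(9)
        db, stats, cs, *_ = random_instance(rng, 2)
        problem = OptimizationProblem(db, stats, cs)
        plain = solve_total_departure(problem)
        multi = multistart_solve(problem, n_starts=1, seed=0)
        assert multi.objective_value == pytest.approx(plain.objective_value, abs=1e-8)

    def test_convexity_makes_all_starts_agree(self):
        rng = np.random.default_rng(10)
        db, stats, cs, *_ = random_instance(rng, 2)
        problem = OptimizationProblem(db, stats, cs)
        values = [multistart_solve(problem, n_starts=k, seed=5).objective_value
                  for k in (1, 3, 5)]
        assert max(values) - min(values) < 1e-6

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(11)
        db, stats, cs, *_ = random_instance(rng, 3)
        problem = OptimizationProblem(db, stats, cs)
        a = multistart_solve(problem, n_starts=4, seed=42)
        b = multistart_solve(problem, n_starts=4, seed=42)
        assert np.array_equal(a.diet.stacked(), b.diet.stacked())
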