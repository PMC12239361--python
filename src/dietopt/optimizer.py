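"""Diet optimization models.

Three model families share one linear(ized) feasible set (nutrient
adequacy, energy band, dietary-guideline rules, acceptability caps):

1. the *TD model* minimizes the total departure from the observed diet,

   ``TD = sum_i ((Opt_i - Obs_i) / SD_i)**2``

   a convex quadratic in the mode-summed consumptions ``Opt_i``;
2. the *MinGHGe/MaxGHGe models* minimize or maximize diet greenhouse-gas
   emissions, a linear objective thanks to the split of every group into
   conventional and organic decision variables;
3. the *grid scan* traces the whole emission range by minimizing TD under
   an additional GHGe equality, stepped by 0.2 kgCO2eq/d.

A meat-cap sensitivity series re-solves MaxGHGe under total-meat limits of
500 down to 200 g/wk.

The quadratic solves use ``scipy.optimize.minimize(method="trust-constr")``
with analytic gradient and constant Hessian; the linear solves use
``scipy.optimize.linprog`` (HiGHS).  Because the TD objective only sees
mode-summed totals, mode assignment can be degenerate; a deterministic
lexicographic second stage ("prefer conventional" for the TD family,
"minimize TD" for the extremum family) makes reported diets reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import Bounds, linprog, minimize
from scipy.optimize import LinearConstraint as ScipyLinearConstraint

from .constraints import ConstraintSet, LinearConstraint
from .food_model import DietVector, FoodDatabase, PopulationStats, diet_totals

__all__ = [
    "SolverOptions",
    "OptimizationProblem",
    "Solution",
    "GridScanResult",
    "total_departure",
    "ghge_coefficients",
    "make_grid",
    "inward_grid_bracket",
    "solve_total_departure",
    "solve_ghge_extremum",
    "grid_scan",
    "meat_cap_sensitivity",
    "multistart_solve",
    "diagnose_infeasibility",
]

OBJECTIVES = ("min_TD", "min_GHGe", "max_GHGe", "min_TD_given_GHGe")


@dataclass(frozen=True)
class SolverOptions:
    """Numerical settings shared by all model solves."""

    feasibility_tol: float = 1e-6  # relative
    optimality_tol: float = 1e-8
    max_iter: int = 3000
    multistart: int = 1
    seed: int = 0
    mode_tiebreak: bool = True  # deterministic secondary objective


@dataclass
class OptimizationProblem:
    """One model instance: data, compiled constraints and an objective."""

    db: FoodDatabase
    stats: PopulationStats
    constraints: ConstraintSet
    objective: str = "min_TD"
    ghge_target: float | None = None
    options: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.objective == "min_TD_given_GHGe" and self.ghge_target is None:
            raise ValueError("min_TD_given_GHGe requires a ghge_target")
        if self.db.n_groups != self.stats.n_groups:
            raise ValueError("database and population stats disagree on group count")


@dataclass
class Solution:
    """An optimized diet with solver status and bookkeeping."""

    status: str  # "optimal" | "infeasible" | "error"
    diet: DietVector | None
    objective_value: float | None
    td: float | None
    active_constraints: list[str] = field(default_factory=list)
    infeasible_provenances: list[str] = field(default_factory=list)
    message: str = ""
    indicators: dict | None = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class GridScanResult:
    """Ordered solutions of the GHGe-constrained departure minimization."""

    targets: np.ndarray  # kgCO2eq/d, strictly increasing by `step`
    solutions: list[Solution]
    step: float
    bracket: tuple[float, float]

    def __post_init__(self) -> None:
        d = np.diff(self.targets)
        if len(d) and not np.allclose(d, self.step, atol=1e-9):
            raise ValueError("grid targets must increase by the step size")

    @property
    def n_levels(self) -> int:
        return len(self.targets)

    def level_name(self, k: int) -> str:
        return f"M{k}"

    def feasible(self) -> list[tuple[float, Solution]]:
        return [(float(g), s) for g, s in zip(self.targets, self.solutions) if s.ok]


def total_departure(diet: DietVector, stats: PopulationStats) -> float:
    """Sum of squared SD-standardized deviations from the observed diet.

    Groups with zero observed SD are excluded from the sum (the
    standardized deviation is undefined there; such groups are governed by
    constraints only).
    """
    mask = stats.sd > 0
    dev = (diet.total[mask] - stats.mean[mask]) / stats.sd[mask]
    return float(np.sum(dev**2))


def ghge_coefficients(db: FoodDatabase) -> np.ndarray:
    """Per-gram GHGe coefficients over the stacked vector (kgCO2eq per g/d)."""
    per_g = db.ghge / 1000.0
    return np.concatenate([per_g[:, 0], per_g[:, 1]])


def make_grid(gmin: float, gmax: float, step: float = 0.2) -> np.ndarray:
    """Emission grid from gmin to gmax inclusive, stepped evenly.

    Levels are computed in integer steps to avoid float accumulation: the
    bracket [1.2, 6.8] with step 0.2 yields exactly 29 levels (M0..M28).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if gmax < gmin - 1e-12:
        raise ValueError("gmax must be >= gmin")
    n = int(np.floor((gmax - gmin) / step + 1e-9)) + 1
    return np.round(gmin + step * np.arange(n), 10)


def inward_grid_bracket(ghge_min: float, ghge_max: float, step: float = 0.2) -> tuple[float, float]:
    """Round the attainable emission range inward onto the grid."""
    lo = np.ceil(ghge_min / step - 1e-9) * step
    hi = np.floor(ghge_max / step + 1e-9) * step
    return float(np.round(lo, 10)), float(np.round(hi, 10))


# --------------------------------------------------------------------------
# internal solver plumbing
# --------------------------------------------------------------------------

def _lp(
    c: np.ndarray,
    cs: ConstraintSet,
    maximize: bool = False,
) -> tuple[str, np.ndarray | None, float | None, str]:
    A_ub, b_ub, A_eq, b_eq = cs.matrices()
    res = linprog(
        -c if maximize else c,
        A_ub=A_ub if len(b_ub) else None, b_ub=b_ub if len(b_ub) else None,
        A_eq=A_eq if len(b_eq) else None, b_eq=b_eq if len(b_eq) else None,
        bounds=(0, None), method="highs",
    )
    if res.status == 0:
        val = float(c @ res.x)
        return "optimal", res.x, val, res.message
    if res.status == 2:
        return "infeasible", None, None, res.message
    if res.status == 3:
        return "unbounded", None, None, res.message
    return "error", None, None, res.message


def _feasible_point(cs: ConstraintSet) -> np.ndarray | None:
    status, x, _, _ = _lp(np.zeros(2 * cs.n_groups), cs)
    return x if status == "optimal" else None


def _td_parts(stats: PopulationStats) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mask = stats.sd > 0
    inv_sd2 = np.zeros(stats.n_groups)
    inv_sd2[mask] = 1.0 / stats.sd[mask] ** 2
    return mask, inv_sd2, stats.mean


def _td_quadratic(stats: PopulationStats, g: int) -> tuple[np.ndarray, np.ndarray]:
    """Hessian and linear term of TD over the stacked vector (constant part dropped)."""
    _, inv_sd2, mean = _td_parts(stats)
    d = np.diag(2.0 * inv_sd2)
    H = np.block([[d, d], [d, d]])
    c_half = -2.0 * inv_sd2 * mean
    return H, np.concatenate([c_half, c_half])


def _polish_kkt(
    cs: ConstraintSet,
    stats: PopulationStats,
    x: np.ndarray,
    active_tol: float = 1e-6,
) -> np.ndarray:
    """Refine a near-optimal QP iterate by solving the KKT system of its
    active set.  The candidate is accepted only if it stays feasible and
    does not worsen the objective; otherwise x is returned unchanged."""
    g = cs.n_groups
    _, inv_sd2, mean = _td_parts(stats)
    H, c = _td_quadratic(stats, g)

    def fun(z: np.ndarray) -> float:
        t = z[:g] + z[g:]
        d = t - mean
        return float(np.sum(inv_sd2 * d * d))

    rows, rhs = [], []
    for con in cs:
        scale = max(1.0, abs(con.rhs))
        if con.sense == "==" or abs(con.value(x) - con.rhs) <= active_tol * scale:
            rows.append(con.coeffs)
            rhs.append(con.rhs)
    for i in np.flatnonzero(x <= active_tol):
        e = np.zeros(2 * g)
        e[i] = 1.0
        rows.append(e)
        rhs.append(0.0)
    if not rows:
        return x
    A = np.array(rows)
    b = np.array(rhs)
    n, m = 2 * g, len(b)
    kkt = np.block([[H, A.T], [A, np.zeros((m, m))]])
    target = np.concatenate([-c, b])
    sol, *_ = np.linalg.lstsq(kkt, target, rcond=None)
    z = sol[:n]
    if np.any(z < -1e-9):
        return x
    z = np.maximum(z, 0.0)
    if cs.violated(z, tol=1e-9):
        return x
    if fun(z) > fun(x) + 1e-10:
        return x
    return z


def _qp_min_td(
    cs: ConstraintSet,
    stats: PopulationStats,
    options: SolverOptions,
    x0: np.ndarray | None = None,
    extra_starts: Sequence[np.ndarray] = (),
) -> tuple[str, np.ndarray | None, str]:
    """Minimize TD over the linear feasible set.

    Runs a trust-region solve from each candidate start (the given warm
    start, a phase-1 LP point, then any extra starts), followed by an
    active-set KKT polish; the first feasible optimized point wins.
    """
    g = cs.n_groups
    _, inv_sd2, mean = _td_parts(stats)
    H, _ = _td_quadratic(stats, g)

    def split_total(x: np.ndarray) -> np.ndarray:
        return x[:g] + x[g:]

    def fun(x: np.ndarray) -> float:
        d = split_total(x) - mean
        return float(np.sum(inv_sd2 * d * d))

    def jac(x: np.ndarray) -> np.ndarray:
        gt = 2.0 * inv_sd2 * (split_total(x) - mean)
        return np.concatenate([gt, gt])

    starts: list[np.ndarray] = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    feas = _feasible_point(cs)
    if feas is None:
        if not starts and not len(extra_starts):
            return "infeasible", None, "phase-1 LP infeasible"
        # phase-1 says infeasible: trust it over stale warm starts
        return "infeasible", None, "phase-1 LP infeasible"
    starts.append(feas)
    starts.extend(np.asarray(s, dtype=float) for s in extra_starts)

    A_ub, b_ub, A_eq, b_eq = cs.matrices()
    scipy_cons = []
    if len(b_ub):
        scipy_cons.append(ScipyLinearConstraint(A_ub, -np.inf, b_ub))
    if len(b_eq):
        scipy_cons.append(ScipyLinearConstraint(A_eq, b_eq, b_eq))
    last_message = ""
    for start in starts:
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Singular Jacobian matrix")
            res = minimize(
                fun, np.maximum(start, 0.0), jac=jac, hess=lambda x: H,
                method="trust-constr", constraints=scipy_cons,
                bounds=Bounds(0, np.inf),
                options={
                    "gtol": options.optimality_tol,
                    "xtol": 1e-11,
                    "maxiter": options.max_iter,
                },
            )
        x = np.maximum(res.x, 0.0)
        x = _polish_kkt(cs, stats, x)
        if not cs.violated(x, options.feasibility_tol):
            return "optimal", x, res.message
        last_message = res.message
    return "error", None, f"no start converged to a feasible point: {last_message}"


def _active_labels(cs: ConstraintSet, x: np.ndarray, tol: float = 1e-5) -> list[str]:
    labels = []
    for con in cs:
        scale = max(1.0, abs(con.rhs))
        if abs(con.value(x) - con.rhs) <= tol * scale:
            labels.append(con.label)
    return labels


def _totals_pin_rows(x: np.ndarray, g: int) -> list[LinearConstraint]:
    """Equality rows fixing each mode-summed total at its current value."""
    rows = []
    totals = x[:g] + x[g:]
    for i in range(g):
        coeffs = np.zeros(2 * g)
        coeffs[i] = coeffs[g + i] = 1.0
        rows.append(LinearConstraint(coeffs, "==", float(totals[i]),
                                     "ghge_target", f"_pin_{i}"))
    return rows


def _prefer_conventional(cs: ConstraintSet, x: np.ndarray) -> np.ndarray:
    """Among mode splits with identical totals, pick the one with the least
    organic mass.  Resolves the organic/conventional degeneracy of the TD
    objective deterministically (the no-emission-preference models then
    report 0% organic when modes are nutritionally identical).  Totals are
    pinned exactly, so the departure value cannot move."""
    g = cs.n_groups
    c = np.concatenate([np.zeros(g), np.ones(g)])
    pinned = cs.extended(_totals_pin_rows(x, g))
    status, x2, _, _ = _lp(c, pinned)
    return x2 if status == "optimal" and x2 is not None else x


def diagnose_infeasibility(cs: ConstraintSet) -> list[str]:
    """Provenance labels of constraints needing slack in an elastic relaxation.

    Solves the elastic LP ``min sum(s)`` with one slack per constraint row;
    rows keeping positive slack at the optimum point to the conflict.
    """
    n = 2 * cs.n_groups
    m = len(cs.constraints)
    if m == 0:
        return []
    rows_ub, rhs_ub = [], []
    for j, con in enumerate(cs.constraints):
        s = np.zeros(m)
        s[j] = 1.0
        if con.sense in ("<=", "=="):
            rows_ub.append(np.concatenate([con.coeffs, -s]))
            rhs_ub.append(con.rhs)
        if con.sense in (">=", "=="):
            rows_ub.append(np.concatenate([-con.coeffs, -s]))
            rhs_ub.append(-con.rhs)
    c = np.concatenate([np.zeros(n), np.ones(m)])
    res = linprog(c, A_ub=np.array(rows_ub), b_ub=np.array(rhs_ub),
                  bounds=(0, None), method="highs")
    if res.status != 0:
        return ["<elastic relaxation failed>"]
    slack = res.x[n:]
    labels = []
    for j, con in enumerate(cs.constraints):
        if slack[j] > 1e-6 * max(1.0, abs(con.rhs)):
            labels.append(f"{con.provenance}:{con.label}")
    return labels


def _finish(
    cs: ConstraintSet,
    stats: PopulationStats,
    x: np.ndarray,
    objective_value: float,
) -> Solution:
    diet = DietVector.from_stacked(x)
    return Solution(
        status="optimal",
        diet=diet,
        objective_value=objective_value,
        td=total_departure(diet, stats),
        active_constraints=_active_labels(cs, x),
    )


# --------------------------------------------------------------------------
# public solves
# --------------------------------------------------------------------------

def _with_ghge_target(
    cs: ConstraintSet, db: FoodDatabase, target: float
) -> ConstraintSet:
    coeffs = ghge_coefficients(db)
    return cs.extended([
        LinearConstraint(coeffs, "==", float(target), "ghge_target",
                         f"ghge_eq_{target:g}", "kgCO2eq/d")
    ])


def solve_total_departure(problem: OptimizationProblem) -> Solution:
    """Minimize the total departure from the observed diet (TD model).

    Also solves each grid-scan level when ``problem.objective`` is
    ``min_TD_given_GHGe`` (the compiled set is extended with the emission
    equality).  The TD objective is convex quadratic, so the reported
    solution is a global minimizer.
    """
    cs = problem.constraints
    if problem.objective == "min_TD_given_GHGe":
        cs = _with_ghge_target(cs, problem.db, problem.ghge_target)
    status, x, message = _qp_min_td(cs, problem.stats, problem.options)
    if status != "optimal":
        return Solution(
            status="infeasible" if status == "infeasible" else "error",
            diet=None, objective_value=None, td=None, message=message,
            infeasible_provenances=(
                diagnose_infeasibility(cs) if status == "infeasible" else []
            ),
        )
    if problem.options.mode_tiebreak:
        x = _prefer_conventional(cs, x)
    diet = DietVector.from_stacked(x)
    td = total_departure(diet, problem.stats)
    return _finish(cs, problem.stats, x, td)


def solve_ghge_extremum(problem: OptimizationProblem, direction: str) -> Solution:
    """Minimize or maximize diet GHGe over the feasible set (LP).

    With the default lexicographic tie-break, the reported diet is the
    minimum-TD point among all emission-optimal diets, making the solution
    unique and reproducible under LP degeneracy.
    """
    if direction not in ("min", "max"):
        raise ValueError("direction must be 'min' or 'max'")
    cs = problem.constraints
    c = ghge_coefficients(problem.db)
    status, x, val, message = _lp(c, cs, maximize=(direction == "max"))
    if status == "unbounded":
        return Solution(status="error", diet=None, objective_value=None, td=None,
                        message="unbounded emission objective "
                                "(missing acceptability cap?)")
    if status != "optimal":
        return Solution(
            status="infeasible" if status == "infeasible" else "error",
            diet=None, objective_value=None, td=None, message=message,
            infeasible_provenances=(
                diagnose_infeasibility(cs) if status == "infeasible" else []
            ),
        )
    if problem.options.mode_tiebreak:
        pinned = _with_ghge_target(cs, problem.db, val)
        status2, x2, _ = _qp_min_td(pinned, problem.stats, problem.options, x0=x)
        if status2 == "optimal":
            x = x2
    sol = _finish(cs, problem.stats, x, float(val))
    return sol


def grid_scan(
    problem: OptimizationProblem,
    gmin: float,
    gmax: float,
    step: float = 0.2,
) -> GridScanResult:
    """Trace minimum-departure diets across the emission range.

    For each grid level ``g`` the TD model is re-solved with the equality
    ``GHGe(diet) = g``.  Infeasible levels are recorded and the scan
    continues.  Consecutive levels warm-start from the previous solution.
    """
    targets = make_grid(gmin, gmax, step)
    # endpoints of the attainable emission segment: convex combinations of
    # the two extremum vertices are feasible starts for every level
    c_ghge = ghge_coefficients(problem.db)
    st_lo, x_lo, g_lo, _ = _lp(c_ghge, problem.constraints)
    st_hi, x_hi, g_hi, _ = _lp(c_ghge, problem.constraints, maximize=True)

    def interpolated_start(g_target: float) -> list[np.ndarray]:
        if st_lo != "optimal" or st_hi != "optimal" or g_hi <= g_lo:
            return []
        lam = np.clip((g_hi - g_target) / (g_hi - g_lo), 0.0, 1.0)
        return [lam * x_lo + (1 - lam) * x_hi]

    solutions: list[Solution] = []
    warm: np.ndarray | None = None
    for g in targets:
        cs = _with_ghge_target(problem.constraints, problem.db, float(g))
        status, x, message = _qp_min_td(
            cs, problem.stats, problem.options, x0=warm,
            extra_starts=interpolated_start(float(g)),
        )
        if status != "optimal":
            solutions.append(Solution(
                status="infeasible" if status == "infeasible" else "error",
                diet=None, objective_value=None, td=None, message=message,
            ))
            continue
        if problem.options.mode_tiebreak:
            x = _prefer_conventional(cs, x)
        diet = DietVector.from_stacked(x)
        solutions.append(_finish(cs, problem.stats, x, total_departure(diet, problem.stats)))
        warm = x

    # Refinement sweeps: the optimal value function of a convex QP is convex
    # in the emission target, so any level violating midpoint convexity is a
    # suboptimal solve; re-solve it starting from the neighbour average
    # (feasible for the mid target on a uniform grid).
    for _ in range(3):
        improved = False
        for j in range(1, len(targets) - 1):
            s_prev, s_here, s_next = solutions[j - 1], solutions[j], solutions[j + 1]
            if not (s_prev.ok and s_here.ok and s_next.ok):
                continue
            bound = 0.5 * (s_prev.td + s_next.td)
            if s_here.td <= bound + 1e-9:
                continue
            cs = _with_ghge_target(problem.constraints, problem.db, float(targets[j]))
            mid = 0.5 * (s_prev.diet.stacked() + s_next.diet.stacked())
            status, x, _ = _qp_min_td(cs, problem.stats, problem.options, x0=mid)
            if status == "optimal":
                if problem.options.mode_tiebreak:
                    x = _prefer_conventional(cs, x)
                diet = DietVector.from_stacked(x)
                td = total_departure(diet, problem.stats)
                if td < s_here.td - 1e-12:
                    solutions[j] = _finish(cs, problem.stats, x, td)
                    improved = True
        if not improved:
            break
    return GridScanResult(targets=targets, solutions=solutions, step=step,
                          bracket=(float(targets[0]), float(targets[-1])) if len(targets)
                          else (gmin, gmax))


def total_meat_constraint(db: FoodDatabase, cap_g_per_week: float) -> LinearConstraint:
    """Total-meat cap (red meat + poultry + processed meat), g/d."""
    mask = (db.tag_mask("is_red_meat") | db.tag_mask("is_poultry")
            | db.tag_mask("is_processed_meat"))
    if not mask.any():
        raise ValueError("no meat-tagged groups in the database")
    coeffs = np.concatenate([mask.astype(float), mask.astype(float)])
    return LinearConstraint(coeffs, "<=", cap_g_per_week / 7.0, "meat_cap",
                            f"total_meat_le_{cap_g_per_week:g}gwk")


def meat_cap_sensitivity(
    problem: OptimizationProblem,
    caps: Sequence[float] = (500.0, 400.0, 300.0, 200.0),
) -> dict[float, Solution]:
    """Re-solve MaxGHGe under decreasing total-meat caps (g/wk).

    Mirrors the question "how far can emissions rise under guideline
    compliance if total meat is also limited?": the attainable maximum is
    non-increasing as the cap tightens.
    """
    out: dict[float, Solution] = {}
    for cap in caps:
        cs = problem.constraints.extended([total_meat_constraint(problem.db, cap)])
        sub = replace(problem, constraints=cs, objective="max_GHGe")
        out[float(cap)] = solve_ghge_extremum(sub, "max")
    return out


def multistart_solve(
    problem: OptimizationProblem,
    n_starts: int | None = None,
    seed: int | None = None,
) -> Solution:
    """Best-of-n solve from randomized starting points (seeded, deterministic).

    The convex formulation makes every start agree on the objective; the
    multistart is kept as a regression guard and for experimentation with
    non-convex variants.
    """
    n = n_starts if n_starts is not None else problem.options.multistart
    if n < 1:
        raise ValueError("n_starts must be >= 1")
    the_seed = problem.options.seed if seed is None else seed
    if problem.objective in ("min_GHGe", "max_GHGe"):
        return solve_ghge_extremum(problem, problem.objective[:3].replace("_", ""))
    cs = problem.constraints
    if problem.objective == "min_TD_given_GHGe":
        cs = _with_ghge_target(cs, problem.db, problem.ghge_target)
    base = _feasible_point(cs)
    if base is None:
        return solve_total_departure(problem)
    rng = np.random.default_rng(the_seed)
    best: Solution | None = None
    diagnostics = []
    for k in range(n):
        x0 = base if k == 0 else np.maximum(base * rng.uniform(0.5, 1.5, base.shape), 0.0)
        status, x, message = _qp_min_td(cs, problem.stats, problem.options, x0=x0)
        if status != "optimal":
            diagnostics.append(f"start {k}: {status} ({message})")
            continue
        if problem.options.mode_tiebreak:
            x = _prefer_conventional(cs, x)
        diet = DietVector.from_stacked(x)
        sol = _finish(cs, problem.stats, x, total_departure(diet, problem.stats))
        if best is None or sol.objective_value < best.objective_value:
            best = sol
    if best is None:
        return Solution(status="error", diet=None, objective_value=None, td=None,
                        message="; ".join(diagnostics) or "all starts failed")
    return best
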