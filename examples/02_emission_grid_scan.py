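"""Trace minimum-departure diets across the attainable emission range.

Each grid level fixes diet GHGe (0.2 kgCO2eq/d steps) and re-minimizes the
departure from the observed diet; the resulting value curve is U-shaped
around the unconstrained optimum.
"""

from dietopt import (
    OptimizationProblem,
    default_scenario,
    grid_scan,
    inward_grid_bracket,
    solve_ghge_extremum,
)

sc = default_scenario(seed=17, n_individuals=2000)
problem = OptimizationProblem(sc.db, sc.stats, sc.constraints)

lo = solve_ghge_extremum(problem, "min")
hi = solve_ghge_extremum(problem, "max")
gmin, gmax = inward_grid_bracket(lo.objective_value, hi.objective_value, 0.2)
print(f"attainable GHGe range: [{lo.objective_value:.2f}, "
      f"{hi.objective_value:.2f}] kgCO2eq/d -> grid [{gmin}, {gmax}]")

scan = grid_scan(problem, gmin, gmax, step=0.2)
print(f"{scan.n_levels} levels (M0..M{scan.n_levels - 1}):")
for k, (g, sol) in enumerate(zip(scan.targets, scan.solutions)):
    if k % 5 == 0 and sol.ok:
        bar = "#" * max(1, int(sol.td / 10))
        print(f"  M{k:<3d} GHGe {g:4.1f}  TD {sol.td:7.1f}  {bar}")

# TD rises toward both ends: pushing emissions far below or above what the
# population already eats requires increasingly unfamiliar diets.
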