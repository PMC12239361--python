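"""Solve the three main diet models on the default synthetic scenario.

Generates a 47-group food database and a 2000-person population, compiles
the nutrient / guideline / acceptability constraints, and solves:
the minimal-departure model (closest compliant diet to the observed one)
and the two emission extremum models.
"""

from dietopt import (
    OptimizationProblem,
    default_scenario,
    diet_totals,
    panel,
    solve_ghge_extremum,
    solve_total_departure,
)
from dietopt.food_model import DietVector

sc = default_scenario(seed=17, n_individuals=2000)
problem = OptimizationProblem(sc.db, sc.stats, sc.constraints)

observed = DietVector.from_totals(sc.stats.mean)
obs = diet_totals(observed, sc.db)
print(f"observed diet:  GHGe {obs.ghge:5.2f} kgCO2eq/d, "
      f"energy {obs.energy_kcal:6.0f} kcal/d")

solutions = {
    "min departure": solve_total_departure(problem),
    "min GHGe": solve_ghge_extremum(problem, "min"),
    "max GHGe": solve_ghge_extremum(problem, "max"),
}
for name, sol in solutions.items():
    p = panel(sol.diet, sc.db, sc.stats, sc.tmrel)
    print(f"{name:14s} GHGe {p.ghge:5.2f} kgCO2eq/d "
          f"({p.ghge_per_1000kcal:4.2f}/1000 kcal), organic {p.organic_share:5.1f}%, "
          f"plant protein {p.plant_protein_share:4.1f}%, cost {p.cost:5.2f} EUR/d, "
          f"TD {p.td:7.2f}")

# The three GHGe figures bracket what guideline-compliant diets can emit:
# the spread is driven almost entirely by how much (and which) meat the
# diet keeps, while all diets stay nutrient-adequate and acceptable.
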