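# dietopt

Diet optimization under nutrient, dietary-guideline and acceptability
constraints, with greenhouse-gas grid scans.

## The problem

National food-based dietary guidelines (FBDG) tell people *what* to eat —
at least 400 g/d of fruit and vegetables, at most 500 g/wk of red meat,
two dairy portions a day — but they rarely say anything about the climate
footprint of the diets that comply. Because guidelines leave wide room
(poultry, for instance, is typically unlimited), two fully compliant,
nutrient-adequate diets can differ several-fold in greenhouse-gas
emissions (GHGe).

`dietopt` quantifies that room. Given a food-group database (nutrient
composition, farm-gate environmental pressures and prices for
conventional and organic production) and a population's observed
consumption statistics, it finds diets that are nutrient-adequate,
guideline-compliant and culturally acceptable, and maps the entire range
of emissions such diets can have. It is aimed at nutritional
epidemiologists and sustainability modelers who want a reproducible,
solver-backed version of this analysis on their own data.

## The models

A diet is a vector of daily consumed grams per food group *i*, split into
conventional and organic quantities (so every environmental indicator is
linear in the decision variables). Three model families share one linear
feasible set:

1. **Minimal departure (TD model).** Find the compliant diet closest to
   what the population already eats:

   ```
   min TD = Σ_i [ (Opt_i − Obs_i) / SD_i ]²
   ```

   where `Opt_i` is the optimized and `Obs_i` the observed (weighted mean)
   consumption of group *i*, and `SD_i` its observed standard deviation.
   This is a convex quadratic program, solved to global optimality.

2. **Emission extrema (MinGHGe / MaxGHGe).** Minimize or maximize diet
   GHGe over the same feasible set — two linear programs whose optima
   bracket what compliant diets can emit.

3. **Grid scan.** For each emission target *g* on a 0.2 kgCO2eq/d grid
   between the extrema, minimize TD subject to `GHGe(diet) = g`. The
   optimal value curve is U-shaped around the TD model's own emission
   level, and every solution carries a full indicator panel.

The feasible set combines: an energy band (±8% of the requirement),
blended male/female nutrient reference bounds with
bioavailability-adjusted iron and zinc floors, the twelve quantitative
guideline rules (fruit & vegetables with a capped fruit-juice credit,
dairy portion counts, weekly meat caps, an added-fat energy-share limit,
zero sweet drinks, ...), and acceptability caps at the 99th (or 95th)
percentile of observed consumption — with cereals coupled into a single
cap on their sum and pulses exempt.

Per-diet indicators: GHGe, cumulative energy demand, land occupation,
monetary cost, emission intensity per 1000 kcal, organic mass share,
plant share of protein, per-rule guideline compliance, and a Health Risk
Score (normalized mean distance of risk-factor exposures from their
theoretical minimum-risk levels, 0–100%).

Because the underlying survey, life-cycle and price databases are not
redistributable, the package ships a first-class synthetic-data module
that generates all inputs with the right statistical structure (47
groups, right-skewed weighted consumptions, organic/conventional
footprint differentials, planted energy misreporters, planted-optimum
test instances).

## Worked example

```python
from dietopt import (OptimizationProblem, default_scenario,
                     solve_total_departure, solve_ghge_extremum, panel)

sc = default_scenario(seed=17, n_individuals=2000)
problem = OptimizationProblem(sc.db, sc.stats, sc.constraints)
for name, sol in {
    "min departure": solve_total_departure(problem),
    "min GHGe": solve_ghge_extremum(problem, "min"),
    "max GHGe": solve_ghge_extremum(problem, "max"),
}.items():
    p = panel(sol.diet, sc.db, sc.stats, sc.tmrel)
    print(name, round(p.ghge, 2), round(p.organic_share, 1), round(p.td, 2))
```

Running `python examples/01_solve_main_models.py` (the same computation,
formatted) prints:

```
observed diet:  GHGe  4.23 kgCO2eq/d, energy   2187 kcal/d
min departure  GHGe  4.42 kgCO2eq/d (1.82/1000 kcal), organic   0.0%, plant protein 39.9%, cost  7.78 EUR/d, TD    8.42
min GHGe       GHGe  1.26 kgCO2eq/d (0.53/1000 kcal), organic  92.1%, plant protein 76.2%, cost  6.67 EUR/d, TD 2462.16
max GHGe       GHGe  9.43 kgCO2eq/d (3.39/1000 kcal), organic  10.0%, plant protein 29.6%, cost 16.51 EUR/d, TD  688.49
```

Read: complying with the guidelines while changing as little as possible
*raises* emissions slightly (4.23 → 4.42 kgCO2eq/d) and contains no
organic food; compliant diets as a class span a seven-fold emission
range, with the low-emission end organic- and plant-protein-rich and the
high-emission end meat-heavy and expensive. The other examples trace the
U-shaped departure curve across that range, show how a total-meat cap
(500 → 200 g/wk) pulls the attainable maximum down, and score diets
against minimum-risk exposure levels.

The same workflow is available from the shell:

```
dietopt generate --seed 17 --out fixtures
dietopt solve --config fixtures/config.yaml
dietopt scan --config fixtures/config.yaml
dietopt sensitivity --config fixtures/config.yaml
```

## Layout

```
src/dietopt/
  food_model.py      domain types, weighted statistics, linear aggregation
  constraints.py     nutrient / guideline / acceptability compilation
  optimizer.py       TD quadratic program, emission LPs, grid scan
  indicators.py      indicator panel, compliance checker, Health Risk Score
  synthetic_data.py  generators: database, population, planted optima, TMREL
  io.py, reporting.py, config.py, cli.py
examples/            one narrative script per capability
docs/methods.md      model assumptions, parameter choices, limitations
```
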