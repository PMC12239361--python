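# Methods

## Decision variables and objective

Each of the 47 food groups appears twice in the decision vector: grams
per day produced conventionally (`q_conv`) and organically (`q_org`).
This parametrization is deliberate. The natural alternative — consumption
per group plus a percent-organic share — makes every environmental
indicator bilinear and the problem non-convex, so global optimality would
rest on multistart luck. With the split, GHGe, cumulative energy demand,
land occupation and cost are linear, the departure objective

TD = Σ_i ((Opt_i − Obs_i) / SD_i)², Opt_i = q_conv,i + q_org,i

is convex quadratic (positive semidefinite: it is flat along the
conventional/organic split of each total), and every model is a convex
program. Percent organic is derived post hoc as q_org / (q_conv + q_org).

Groups with zero observed SD are excluded from the TD sum (the
standardized deviation is undefined); they remain governed by
constraints only. A multistart wrapper exists for parity with non-convex
experimentation, but for the shipped convex formulation all starts agree
to 1e-6 and it functions as a regression check.

## Constraint set

All constraints are linear in the decision vector.

* **Energy band**: total energy within ±8% of the population mean energy
  requirement.
* **Nutrient bounds**: lower/upper reference values per nutrient, blended
  across three population strata (males; females with high iron
  requirements; females with low/moderate iron requirements) with weights
  0.5 / 0.125 / 0.375 — a plausible adult split in which half of women
  have elevated iron needs. The shipped bounds are round adult reference
  figures (protein 54–64 g/d by stratum, fiber 30 g/d, calcium 950 mg/d,
  vitamin C 110 mg/d, sodium ≤ 3–3.5 g/d, free sugars ≤ 90–100 g/d);
  users supply their own table in production use.
* **Iron/zinc bioavailability**: the published absorption equations
  behind this kind of analysis are not redistributable, so the absorption
  model is a plug-in registry. The default parametric model modulates a
  base fraction (iron 0.10, zinc 0.25) by a saturating vitamin-C
  enhancement and a fiber (phytate-proxy) inhibition, clipped to
  [0.03, 0.35]. For constraint compilation the fraction is evaluated once
  at the observed-mean diet, keeping the bound linear; post-hoc
  indicators use the full model at the solution. The constraint compares
  absorbable intake to deficiency-derived floors (defaults 0.8 mg/d iron,
  1.8 mg/d zinc).
* **Dietary-guideline rules** (twelve, with main-scenario defaults):
  fruit & vegetables ≥ 400 g/d with fruit juice credited up to one 150 g
  portion — compiled exactly as the linear pair `F+V+J ≥ 400` and
  `F+V ≥ 250`, since `min(J, 150)` enters a lower bound; juice ≤ 150 g/d;
  nuts ≥ 15 g/d (the guideline wording says 30 g/d, but published
  compliant model diets all sit at 15 g/d, implying 15 was the operative
  bound — both are in config, 15 is the default); pulses and wholegrains
  ≥ 400 g/wk each; dairy exactly 2 portions/d (portion sizes: milk 150,
  cheese 30, yogurt 125, petits suisses 120, cottage cheese 100 g; an
  optional ±δ band relaxes the equality, default δ=0 because the sense of
  the guideline is not stated); red meat ≤ 500 g/wk; processed meat
  ≤ 150 g/wk; total seafood ≥ 200 g/wk; fatty fish ≥ 100 g/wk (the
  guideline table's "2 portions of 100 g" phrasing conflicts with its own
  printed daily value of 14.28 g/d = one portion; the printed daily value
  wins); added-fat energy ≤ 16% of total energy, linearized as
  `E_fat − 0.16·E_total ≤ 0` (exact whenever energy is positive, which
  the energy band guarantees); sweet drinks = 0. No food-group rules for
  salt or sugary foods: the sodium and free-sugar caps live in the
  nutrient set. An optional alcohol cap exists in config, off by default.
* **Acceptability**: per-group caps at the weighted 99th percentile of
  observed consumption (95th in a sensitivity run). All cereal groups
  (refined + wholegrain) are *coupled*: one cap on their summed
  consumption, at the percentile of the observed sums, so any one cereal
  may exceed its own percentile. Pulses are exempt (observed consumption
  is too low to anchor a ceiling). When stats arrive from files without
  stored sum-percentiles, the coupled cap falls back to the sum of
  per-group percentiles (strictly looser; flagged in the stats sidecar).
* **Weekly→daily conversion** is exact (÷7) in every compiled constraint;
  a display helper reproduces the rounded values guideline tables print.

## Solvers and numerics

Linear objectives go to `scipy.optimize.linprog` (HiGHS). The quadratic
departure models use `scipy.optimize.minimize(trust-constr)` with
analytic gradient and constant Hessian, started from a phase-1 LP point
(plus a warm start along the grid), followed by an **active-set KKT
polish**: the equality system of the constraints active at the iterate is
solved directly (least-squares on the KKT matrix) and the candidate is
accepted only if it stays feasible and does not worsen the objective.
The polish removes the interior-point slack of the trust-region method
and is what brings planted-optimum recovery to machine precision.

Feasibility tolerance is 1e-6 (relative), optimality 1e-8; both are
configurable. Infeasible problems are diagnosed with an elastic LP
(minimum total slack); constraints retaining slack are reported with
their provenance (nutrient / guideline / acceptability / ...).

Degeneracy and tie-breaking: when production modes are nutritionally
identical, the TD objective cannot distinguish conventional from organic.
Two deterministic second stages make reported diets reproducible: for
departure-family models, an LP minimizes total organic mass with all
totals pinned by equality (so the departure value cannot move) — this is
why no-emission-preference models report 0% organic; for the emission
extremum models, a secondary QP minimizes TD among all emission-optimal
diets (on by default, toggleable).

Grid scan: levels use an *equality* GHGe constraint (a ±step/2 band mode
is available in config). The bracket is the attainable range from the
extremum LPs rounded inward onto the grid. Because the optimal value of
a convex QP is convex in the right-hand side, the scan runs refinement
sweeps: any level whose TD violates midpoint convexity against its
neighbours is re-solved starting from the neighbour average (which is
feasible for the mid target on a uniform grid). The scan reports
infeasible levels rather than dropping them.

## Indicators

* Emission intensity = 1000 × GHGe / energy (identity-tested).
* Organic share is **mass-based** (g organic / g total). The base is a
  modeling choice — energy- or expenditure-based shares are alternatives —
  and mass is the plainest reading of "share of organic food in the
  diet"; the panel exposes the diet vector so other bases are one line
  away.
* Plant protein share uses a per-group plant-protein fraction from the
  database (1 for plant groups, 0 for animal, intermediate for mixed
  dishes).
* Guideline compliance is re-checked *independently* of the constraint
  compiler: the juice credit as a true `min()`, the added-fat rule as a
  true ratio. Every feasible optimizer solution must pass this checker —
  a standing cross-module contract in the test suite.
* **Health Risk Score**: per risk factor, the deviation of the diet's
  exposure from its minimum-risk level (TMREL), normalized by the
  distance to a maximum-deviation reference and clipped to [0, 1]; the
  HRS is 100 × the weighted mean (equal weights by default; the table
  accepts weights). Deviations count only on the risky side — excess for
  harmful factors, shortfall for protective ones — so exceeding a
  protective target (e.g. wholegrains above the TMREL) adds no risk;
  a symmetric reading would make the direction field meaningless. The
  score is a distance metric, not a burden estimate, and its absolute
  level depends on the factor set in the TMREL table; only its endpoint
  contract (0% / 100%) and ordering behaviour are asserted. The shipped
  table holds 12 factors at round GBD-style levels (fruit 250, vegetables
  360, wholegrains 145, nuts 21, legumes 60, fish 28, dairy 435 g/d
  protective; red meat 23, processed meat 2, sugary beverages 3 g/d and
  sodium 2 g/d harmful; fiber 24 g/d protective).
* The continuous guideline-adherence score used in the source literature
  (component-weighted, with an energy penalty) is **not** reproduced —
  its weights are not public; the panel reports per-rule booleans and a
  satisfied-rule count instead.

## Synthetic data

The generator emulates the inputs this analysis consumes, not any real
cohort:

* **Database**: 47 groups × 2 modes. Archetype compositions per 100 g and
  farm-gate footprints per kg are round literature-range values (beef
  ~28 kgCO2eq/kg conventional, pulses ~0.9, vegetables 0.6–1.2), given
  ±5% seeded multiplicative jitter. Organic multipliers are drawn per
  group: GHGe 0.65–0.85 of conventional for plant groups, 0.9–1.1 for
  animal groups (so low-emission diets *tend* to go organic without the
  outcome being hard-coded), land occupation 1.1–1.5×, cumulative energy
  demand 0.75–0.95×, price premium 1.3–1.8×. Composition is identical
  across modes: production method changes the footprint and price, not
  the food.
* **Population** (default 2000 individuals): consumptions are lognormal —
  `x_ig = exp(μ_g + 0.8·z_ig + 0.25·u_i)` with a per-individual appetite
  factor `u_i`, μ_g set so the analytic mean equals the archetype mean
  (observed diet ≈ 2200 kcal/d, ≈ 4.2 kgCO2eq/d). Sampling weights are
  lognormal (σ=0.3); energy requirements are normal (2580 ± 200 kcal/d);
  organic-frequency answers on the five-point scale come from a
  per-individual Beta(2, 5) propensity through a binomial draw. Five
  percent of individuals are *planted* as energy misreporters (diets
  scaled to intake/requirement ratios of 0.20 or 2.20), so the filter has
  exact ground truth; a handful of emergent tail cases is expected and
  realistic, since the cut-offs (0.35, 1.93) are themselves distribution
  percentiles.
* **Weighted statistics**: weighted SD normalizes by total weight; the
  weighted percentile is the left-continuous inverse of the weighted
  empirical CDF (lowest value whose cumulative weight fraction ≥ p),
  fixed and tested against a weight-expansion oracle because no standard
  definition is universal.
* **Planted optima**: variant A sets the observed means equal to a
  constructed guideline-compliant diet, so the full model must return it
  with TD = 0; variant B leaves one binding cap, whose optimum is the
  observed mean clipped to the cap in closed form.

What the generator does **not** emulate: item-level (260+ foods)
granularity, consumption zero-inflation, correlation between food
preferences and organic propensity, regional price structure, or
seasonal variation. Passing tests therefore demonstrate correctness of
the statistical and optimization machinery on structurally realistic
inputs, not reproduction of any real population's numbers: the published
figures from the motivating analysis (emission range 1.16–6.99
kgCO2eq/d) depend on confidential survey, LCA and price databases,
whereas the default synthetic scenario spans about 1.3–9.4 kgCO2eq/d —
the same qualitative structure (U-shaped departure curve, organic-rich
low-emission end, meat-driven high end) with different absolute values.

## Problem sizes and defaults

The default scenario uses 2000 individuals and 47 groups; a full run —
three main models, a ~40-level grid scan with refinement, four meat caps,
and both acceptability levels — takes about a minute on one CPU.
Examples and the acceptance script use seed 17 unless overridden; every
random draw flows from a single integer seed, and generator output is
bit-reproducible per seed.

## Known limitations

* Nutrient reference values, deficiency floors and TMREL levels are
  plausible placeholders, not an authoritative extraction of any
  regulatory table; swap in real tables via config for substantive use.
* The acceptability fallback for file-loaded stats (sum of per-group
  percentiles) is looser than the percentile-of-sums cap the generator
  computes.
* The bioavailability constraint linearizes absorption at the observed
  diet; a diet far from observed composition would shift the true
  fraction (the post-hoc indicator reports the full model, so the
  discrepancy is visible).
* LP vertex reporting depends on the tie-break stage for uniqueness;
  turning `mode_tiebreak` off returns whichever optimal vertex HiGHS
  lands on.
* The non-convex percent-organic parametrization is not implemented —
  the convex split formulation answers the same questions with global
  guarantees.
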