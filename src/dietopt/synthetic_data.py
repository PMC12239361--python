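"""Synthetic food databases, populations and risk-factor tables.

No raw survey, life-cycle or price data ship with the package; this module
generates inputs with the statistical structure the analysis assumes:

* a 47-group food database in two production modes, with plausible
  nutrient profiles per 100 g, farm-gate footprints (GHGe, cumulative
  energy demand, land occupation) and prices per kg.  Animal groups carry
  much higher GHGe per kg than plant groups; organic production lowers
  GHGe for plant groups (roughly 0.65-0.85 of conventional), is mixed for
  animal groups, uses more land, and commands a price premium;
* an individual-level population with right-skewed (lognormal)
  consumptions, sampling weights, a five-point organic-frequency answer
  per group, energy requirements, and a planted share of energy
  misreporters so the filtering step has a known ground truth;
* instances with *planted optima* for end-to-end solver verification;
* a small TMREL risk-factor table for the Health Risk Score.

Everything is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constraints import (
    AcceptabilityConfig,
    BioavailabilityParams,
    ConstraintSet,
    FbdgConfig,
    NutrientReference,
    blend_reference_values,
    compile_constraints,
)
from .food_model import (
    DietVector,
    FoodDatabase,
    FoodGroup,
    Individual,
    PopulationStats,
    aggregate_population_stats,
    diet_totals,
)
from .indicators import RiskFactor, TmrelTable

__all__ = [
    "GeneratorSpec",
    "generate_food_db",
    "generate_population",
    "coupling_sets",
    "population_stats",
    "default_nutrient_references",
    "default_bioavailable_lower",
    "default_scenario",
    "Scenario",
    "PlantedInstance",
    "plant_known_optimum",
    "reference_feasible_diet",
    "tmrel_fixture",
]

NUTRIENTS = (
    "energy_kcal", "protein_g", "fiber_g", "calcium_mg", "iron_mg",
    "zinc_mg", "vitamin_c_mg", "sodium_mg", "free_sugars_g",
)

# ---------------------------------------------------------------------------
# Base archetypes for the 47 optimization groups.
# Columns: name, category, tags, observed mean g/d, GHGe kgCO2eq/kg,
# CED MJ/kg, LO m2/kg, price EUR/kg, plant-protein fraction,
# nutrients per 100 g (kcal, protein g, fiber g, Ca mg, Fe mg, Zn mg,
# vitamin C mg, Na mg, free sugars g).
# Footprints and compositions are round archetype values in the ranges
# food-composition and farm-gate LCA tables report for these groups.
# ---------------------------------------------------------------------------
_G = [
    # name, category, tags, mean, ghge, ced, lo, price, ppf, nutrients
    ("beef", "animal", ("is_red_meat",), 30, 28.0, 45, 30, 12.0, 0.0,
     (250, 26, 0, 15, 2.6, 6.0, 0, 70, 0)),
    ("lamb", "animal", ("is_red_meat",), 8, 30.0, 48, 35, 15.0, 0.0,
     (280, 25, 0, 15, 2.2, 4.5, 0, 75, 0)),
    ("pork", "animal", ("is_red_meat",), 25, 7.0, 25, 12, 9.0, 0.0,
     (240, 26, 0, 15, 1.0, 2.5, 0, 70, 0)),
    ("poultry", "animal", ("is_poultry",), 24, 5.5, 22, 8, 9.0, 0.0,
     (170, 27, 0, 12, 1.0, 1.5, 0, 80, 0)),
    ("processed_meat", "animal", ("is_processed_meat",), 30, 9.0, 28, 12, 12.0, 0.0,
     (300, 17, 0, 20, 1.3, 2.0, 0, 1200, 0.5)),
    ("offal", "animal", (), 2, 10.0, 20, 10, 8.0, 0.0,
     (130, 20, 0, 10, 8.0, 3.5, 5, 90, 0)),
    ("eggs", "animal", (), 11, 3.5, 15, 6, 5.0, 0.0,
     (140, 13, 0, 55, 1.8, 1.3, 0, 130, 0)),
    ("milk", "animal", ("is_dairy",), 59, 1.3, 6, 1.5, 1.1, 0.0,
     (47, 3.3, 0, 120, 0.05, 0.4, 1, 45, 0)),
    ("cheese", "animal", ("is_dairy",), 35, 7.5, 30, 10, 12.0, 0.0,
     (350, 24, 0, 750, 0.3, 3.5, 0, 700, 0)),
    ("yogurt", "animal", ("is_dairy",), 80, 1.6, 8, 2.0, 2.5, 0.0,
     (60, 4, 0, 130, 0.1, 0.5, 1, 50, 4)),
    ("petits_suisses", "animal", ("is_dairy",), 10, 1.8, 9, 2.2, 3.0, 0.0,
     (110, 9, 0, 110, 0.1, 0.5, 0, 35, 3)),
    ("cottage_cheese", "animal", ("is_dairy",), 15, 1.7, 9, 2.2, 3.0, 0.0,
     (100, 8, 0, 90, 0.1, 0.5, 0, 40, 3)),
    ("plant_substitutes", "plant", (), 40, 1.0, 9, 3.0, 3.5, 1.0,
     (80, 8, 1.5, 120, 1.8, 0.9, 0, 300, 1)),
    ("lean_fish", "animal", ("is_fish",), 25, 5.0, 25, 2.0, 14.0, 0.0,
     (100, 22, 0, 20, 0.5, 0.5, 0, 90, 0)),
    ("fatty_fish", "animal", ("is_fish", "is_fatty_fish"), 15, 4.5, 22, 2.0, 13.0, 0.0,
     (200, 20, 0, 15, 1.0, 0.6, 0, 80, 0)),
    ("shellfish", "animal", ("is_fish",), 8, 8.0, 30, 1.0, 16.0, 0.0,
     (90, 18, 0, 50, 2.5, 2.0, 0, 300, 0)),
    ("butter", "fat", ("is_added_fat",), 6, 9.0, 35, 12, 8.0, 0.0,
     (740, 0.7, 0, 15, 0, 0.1, 0, 10, 0.5)),
    ("cream", "fat", ("is_added_fat",), 7, 4.0, 18, 5, 4.0, 0.0,
     (300, 2.3, 0, 80, 0.1, 0.3, 0, 35, 3)),
    ("vegetable_oil", "fat", ("is_added_fat",), 15, 2.5, 15, 10, 3.5, 1.0,
     (900, 0, 0, 0, 0, 0, 0, 0, 0)),
    ("margarine", "fat", ("is_added_fat",), 5, 2.8, 16, 8, 4.0, 1.0,
     (720, 0.2, 0, 5, 0, 0, 0, 90, 0)),
    ("olive_oil", "fat", ("is_added_fat",), 8, 3.2, 18, 12, 7.0, 1.0,
     (900, 0, 0, 0, 0.1, 0, 0, 0, 0)),
    ("refined_bread", "plant", ("is_refined_cereal",), 70, 1.1, 9, 2.5, 3.0, 1.0,
     (270, 9, 3, 30, 1.1, 0.9, 0, 500, 2)),
    ("refined_pasta", "plant", ("is_refined_cereal",), 40, 1.5, 9, 3.0, 2.2, 1.0,
     (130, 4.5, 2, 10, 0.6, 0.6, 0, 2, 0.5)),
    ("white_rice", "plant", ("is_refined_cereal",), 25, 3.0, 12, 2.5, 2.5, 1.0,
     (130, 2.7, 1, 5, 0.2, 0.6, 0, 1, 0)),
    ("breakfast_cereals", "plant", ("is_refined_cereal",), 5, 2.0, 12, 3.0, 4.0, 1.0,
     (380, 8, 4, 25, 4.0, 1.5, 0, 400, 20)),
    ("wholegrain_bread", "plant", ("is_wholegrain",), 25, 1.1, 9, 3.0, 3.5, 1.0,
     (250, 10, 7, 35, 2.5, 1.8, 0, 450, 2)),
    ("wholegrain_pasta", "plant", ("is_wholegrain",), 15, 1.5, 9, 3.5, 2.8, 1.0,
     (135, 5.5, 4.5, 15, 1.3, 1.1, 0, 2, 0.5)),
    ("brown_rice", "plant", ("is_wholegrain",), 10, 3.0, 12, 2.8, 3.0, 1.0,
     (135, 3, 2.5, 8, 0.5, 0.8, 0, 2, 0)),
    ("oats_muesli", "plant", ("is_wholegrain",), 8, 1.3, 10, 3.5, 3.8, 1.0,
     (370, 12, 9, 50, 4.0, 3.0, 0, 20, 8)),
    ("potatoes", "plant", (), 24, 0.5, 3, 0.8, 1.3, 1.0,
     (85, 2, 2, 8, 0.4, 0.3, 10, 5, 0)),
    ("pulses", "plant", ("is_pulse",), 17, 0.9, 5, 4.0, 2.8, 1.0,
     (110, 8, 7.5, 45, 2.2, 1.2, 1, 5, 0)),
    ("leafy_vegetables", "plant", ("is_vegetable",), 60, 1.2, 6, 1.0, 3.5, 1.0,
     (25, 2.5, 2.5, 90, 1.8, 0.5, 35, 30, 1)),
    ("root_vegetables", "plant", ("is_vegetable",), 70, 0.6, 3, 0.7, 1.8, 1.0,
     (35, 1, 3, 35, 0.4, 0.3, 6, 50, 4)),
    ("fruiting_vegetables", "plant", ("is_vegetable",), 120, 1.1, 6, 0.6, 2.3, 1.0,
     (22, 1, 1.5, 12, 0.4, 0.2, 18, 5, 2.5)),
    ("other_vegetables", "plant", ("is_vegetable",), 105, 0.8, 4, 0.8, 2.2, 1.0,
     (30, 1.8, 2.5, 45, 0.7, 0.3, 40, 15, 2)),
    ("temperate_fruit", "plant", ("is_fruit",), 150, 0.45, 3, 1.5, 2.3, 1.0,
     (55, 0.4, 2.2, 8, 0.2, 0.1, 6, 1, 10)),
    ("citrus", "plant", ("is_fruit",), 50, 0.7, 4, 1.5, 2.0, 1.0,
     (45, 0.8, 1.8, 30, 0.2, 0.1, 50, 1, 8)),
    ("tropical_fruit", "plant", ("is_fruit",), 50, 0.9, 5, 2.0, 2.2, 1.0,
     (80, 1, 2.5, 8, 0.4, 0.2, 12, 1, 14)),
    ("berries", "plant", ("is_fruit",), 15, 1.5, 6, 2.0, 6.0, 1.0,
     (45, 0.8, 4, 25, 0.5, 0.3, 30, 1, 6)),
    ("dried_fruit", "plant", ("is_fruit",), 5, 1.8, 8, 3.0, 8.0, 1.0,
     (280, 2.5, 7, 60, 2.0, 0.6, 2, 10, 55)),
    ("fruit_juice", "beverage", ("is_fruit_juice",), 85, 0.8, 5, 1.5, 1.8, 1.0,
     (45, 0.4, 0.2, 10, 0.2, 0.05, 30, 2, 9.5)),
    ("nuts", "plant", ("is_nuts",), 8, 1.5, 12, 8.0, 14.0, 1.0,
     (620, 18, 8, 90, 3.0, 3.0, 1, 3, 4)),
    ("sweet_drinks", "beverage", ("is_sweet_drink",), 47, 0.5, 4, 0.5, 1.2, 1.0,
     (40, 0, 0, 5, 0, 0, 0, 10, 9.5)),
    ("alcoholic_beverages", "beverage", (), 128, 1.3, 8, 2.0, 4.0, 1.0,
     (70, 0.3, 0, 8, 0.3, 0.03, 0, 5, 2)),
    ("sweet_fat_foods", "mixed", (), 73, 3.5, 15, 5.0, 8.0, 0.3,
     (430, 6, 2, 60, 1.5, 0.8, 0, 250, 30)),
    ("mixed_dishes", "mixed", (), 29, 3.8, 14, 4.0, 7.0, 0.35,
     (180, 8, 1.5, 50, 1.2, 1.2, 5, 450, 2)),
    ("snacks", "mixed", (), 11, 5.5, 18, 6.0, 8.0, 0.2,
     (280, 12, 1.5, 30, 1.2, 1.5, 2, 600, 2)),
]

assert len(_G) == 47

#: Display regrouping of the 47 optimization groups into 25 broader
#: categories (presentation only; never used by the optimizer).
DISPLAY_REGROUPING: dict[str, str] = {
    "beef": "beef_lamb", "lamb": "beef_lamb", "pork": "pork",
    "poultry": "poultry", "processed_meat": "processed_meat", "offal": "offal",
    "eggs": "eggs", "milk": "milk",
    "cheese": "dairy_products", "yogurt": "dairy_products",
    "petits_suisses": "dairy_products", "cottage_cheese": "dairy_products",
    "plant_substitutes": "substitutes",
    "lean_fish": "fish", "fatty_fish": "fish", "shellfish": "fish",
    "butter": "animal_fat", "cream": "other_fat",
    "vegetable_oil": "vegetable_fat", "margarine": "vegetable_fat",
    "olive_oil": "vegetable_fat",
    "refined_bread": "refined_cereals", "refined_pasta": "refined_cereals",
    "white_rice": "refined_cereals", "breakfast_cereals": "refined_cereals",
    "wholegrain_bread": "wholegrain_products", "wholegrain_pasta": "wholegrain_products",
    "brown_rice": "wholegrain_products", "oats_muesli": "wholegrain_products",
    "potatoes": "potatoes", "pulses": "pulses",
    "leafy_vegetables": "vegetables", "root_vegetables": "vegetables",
    "fruiting_vegetables": "vegetables", "other_vegetables": "vegetables",
    "temperate_fruit": "fruit", "citrus": "fruit", "tropical_fruit": "fruit",
    "berries": "fruit", "dried_fruit": "fruit",
    "fruit_juice": "fruit_juice", "nuts": "nuts",
    "sweet_drinks": "sweet_drinks", "alcoholic_beverages": "alcoholic_beverages",
    "sweet_fat_foods": "sff", "mixed_dishes": "mixed_dishes", "snacks": "snack",
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic-data generator (the study conditions).

    Consumptions are lognormal: individual i's intake of group g is
    ``exp(mu_g + sigma_within * z_ig + appetite_sigma * u_i)`` with ``mu_g``
    set so the analytic mean equals the group's archetype mean.  Organic
    GHGe multipliers are drawn per group from category-specific ranges
    (plant production benefits most, animal production little); organic
    prices carry a premium; organic land occupation is higher.
    """

    n_groups: int = 47
    n_individuals: int = 2000
    seed: int = 17
    sigma_within: float = 0.8  # per-group log-dispersion of intake
    appetite_sigma: float = 0.25  # individual-level common factor
    weight_sigma: float = 0.3  # lognormal sampling-weight dispersion
    eer_mean: float = 2580.0  # kcal/d mean energy requirement
    eer_sd: float = 200.0
    misreporter_fraction: float = 0.05
    db_jitter: float = 0.05  # multiplicative noise on archetype values
    organic_ghge_mult: dict = field(default_factory=lambda: {
        "plant": (0.65, 0.85), "beverage": (0.7, 0.9), "mixed": (0.75, 0.95),
        "fat": (0.7, 0.9), "animal": (0.9, 1.1), "other": (0.8, 1.0),
    })
    organic_ced_mult: tuple[float, float] = (0.75, 0.95)
    organic_lo_mult: tuple[float, float] = (1.1, 1.5)
    organic_price_premium: tuple[float, float] = (1.3, 1.8)
    mean_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_groups != len(_G):
            raise ValueError(f"n_groups must be {len(_G)} (the archetype table size)")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be at least 1")
        if self.sigma_within < 0 or self.appetite_sigma < 0:
            raise ValueError("dispersions must be non-negative")
        if not 0 <= self.misreporter_fraction < 1:
            raise ValueError("misreporter_fraction must be in [0, 1)")


def generate_food_db(spec: GeneratorSpec | None = None) -> FoodDatabase:
    """Generate the 47-group x 2-mode food database.

    Archetype compositions and footprints receive seeded multiplicative
    jitter; organic-mode footprints and prices are the conventional values
    scaled by per-group multipliers drawn from the spec's category ranges.
    Nutrient composition is identical across modes (the production mode
    changes the footprint and the price, not the food).
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    g = len(_G)
    groups = []
    for i, row in enumerate(_G):
        name, category, tags = row[0], row[1], row[2]
        groups.append(FoodGroup(id=i, name=name, category=category,
                                **{t: True for t in tags}))
    base_nutr = np.array([row[9] for row in _G], dtype=float)  # (G, K)
    ghge_c = np.array([row[4] for row in _G], dtype=float)
    ced_c = np.array([row[5] for row in _G], dtype=float)
    lo_c = np.array([row[6] for row in _G], dtype=float)
    price_c = np.array([row[7] for row in _G], dtype=float)
    ppf = np.array([row[8] for row in _G], dtype=float)

    def jitter(shape) -> np.ndarray:
        return np.exp(rng.normal(0.0, spec.db_jitter, shape))

    nutr = base_nutr * jitter(base_nutr.shape)
    ghge_c = ghge_c * jitter(g)
    ced_c = ced_c * jitter(g)
    lo_c = lo_c * jitter(g)
    price_c = price_c * jitter(g)

    ghge_mult = np.empty(g)
    for i, grp in enumerate(groups):
        lo_m, hi_m = spec.organic_ghge_mult[grp.category]
        ghge_mult[i] = rng.uniform(lo_m, hi_m)
    ced_mult = rng.uniform(*spec.organic_ced_mult, g)
    lo_mult = rng.uniform(*spec.organic_lo_mult, g)
    price_mult = rng.uniform(*spec.organic_price_premium, g)

    density = np.stack([nutr, nutr], axis=1)  # (G, 2, K), modes identical
    return FoodDatabase(
        groups=groups,
        nutrients=list(NUTRIENTS),
        density=density,
        ghge=np.stack([ghge_c, ghge_c * ghge_mult], axis=1),
        ced=np.stack([ced_c, ced_c * ced_mult], axis=1),
        lo=np.stack([lo_c, lo_c * lo_mult], axis=1),
        price=np.stack([price_c, price_c * price_mult], axis=1),
        plant_protein_frac=ppf,
    )


_MODALITIES = ("never", "rarely", "half-of-time", "often", "always")


def generate_population(
    spec: GeneratorSpec | None = None,
    db: FoodDatabase | None = None,
) -> list[Individual]:
    """Generate individual-level consumptions, weights and organic answers.

    A fraction ``misreporter_fraction`` of individuals is planted outside
    the energy-reporting band (half scaled far below, half far above), so
    the misreporter filter has an exact ground truth per seed.
    """
    spec = spec or GeneratorSpec()
    db = db if db is not None else generate_food_db(spec)
    rng = np.random.default_rng(spec.seed + 1)
    n, g = spec.n_individuals, db.n_groups
    base_mean = np.array([row[3] for row in _G], dtype=float) * spec.mean_scale
    s2 = spec.sigma_within**2 + spec.appetite_sigma**2
    mu = np.log(base_mean) - s2 / 2.0
    u = rng.normal(0.0, 1.0, n)  # appetite factor
    z = rng.normal(0.0, 1.0, (n, g))
    x = np.exp(mu[None, :] + spec.sigma_within * z + spec.appetite_sigma * u[:, None])
    weights = np.exp(rng.normal(0.0, spec.weight_sigma, n))
    eer = np.clip(rng.normal(spec.eer_mean, spec.eer_sd, n), 1600, None)
    e_per_g = db.nutrient_per_gram("energy_kcal")[:, 0]
    propensity = rng.beta(2.0, 5.0, n)  # individual organic inclination
    modality_idx = rng.binomial(4, propensity[:, None], (n, g))

    # plant misreporters: scale whole diets to land outside [0.35, 1.93]
    k = int(round(spec.misreporter_fraction * n))
    planted = rng.choice(n, size=k, replace=False)
    low_ratio, high_ratio = 0.20, 2.20
    for j, idx in enumerate(sorted(planted)):
        target = low_ratio if j % 2 == 0 else high_ratio
        ei = float(x[idx] @ e_per_g)
        x[idx] *= target * eer[idx] / ei

    population = []
    for i in range(n):
        population.append(Individual(
            consumptions=x[i],
            organic_frequency=[_MODALITIES[m] for m in modality_idx[i]],
            weight=float(weights[i]),
            energy_requirement=float(eer[i]),
            energy_intake=float(x[i] @ e_per_g),
        ))
    return population


def coupling_sets(db: FoodDatabase) -> list[tuple[int, ...]]:
    """The coupled acceptability sets: all cereal groups (refined + wholegrain)."""
    mask = db.tag_mask("is_refined_cereal") | db.tag_mask("is_wholegrain")
    return [tuple(int(i) for i in np.flatnonzero(mask))]


def population_stats(
    population: Sequence[Individual], db: FoodDatabase
) -> PopulationStats:
    """Aggregate a (filtered) population with the cereal coupling sums."""
    return aggregate_population_stats(population, coupling=coupling_sets(db))


#: Strata weights for blending male / female reference values into the
#: average-individual bounds (males, females with high iron requirements,
#: females with low/moderate iron requirements).
DEFAULT_STRATA_WEIGHTS = {"male": 0.5, "female_high_iron": 0.125,
                          "female_low_mod_iron": 0.375}


def default_nutrient_references() -> list[NutrientReference]:
    """Blended average-individual nutrient bounds used by the default scenario.

    Values are round reference-intake figures for adults; each is blended
    across the three population strata with :data:`DEFAULT_STRATA_WEIGHTS`.
    Iron and zinc are handled separately through bioavailability-adjusted
    deficiency thresholds, not here.
    """
    strata = DEFAULT_STRATA_WEIGHTS
    table = {
        # nutrient: (male (lower, upper), female_high (l, u), female_low (l, u), unit)
        "protein_g": ((64, None), (54, None), (54, None), "g/d"),
        "fiber_g": ((30, None), (30, None), (30, None), "g/d"),
        "calcium_mg": ((950, 2500), (950, 2500), (950, 2500), "mg/d"),
        "vitamin_c_mg": ((110, 2000), (110, 2000), (110, 2000), "mg/d"),
        "sodium_mg": ((None, 3500), (None, 3000), (None, 3000), "mg/d"),
        "free_sugars_g": ((None, 100), (None, 90), (None, 90), "g/d"),
    }
    refs = []
    for nutrient, (m, fh, fl, unit) in table.items():
        refs.append(blend_reference_values(
            {
                "male": NutrientReference(nutrient, *m, unit=unit),
                "female_high_iron": NutrientReference(nutrient, *fh, unit=unit),
                "female_low_mod_iron": NutrientReference(nutrient, *fl, unit=unit),
            },
            strata,
        ))
    return refs


def default_bioavailable_lower() -> dict[str, float]:
    """Deficiency-prevalence-derived lower bounds on absorbable minerals, mg/d."""
    return {"iron": 0.8, "zinc": 1.8}


@dataclass
class Scenario:
    """A fully generated main-scenario instance."""

    spec: GeneratorSpec
    db: FoodDatabase
    population: list[Individual]
    stats: PopulationStats
    constraints: ConstraintSet
    tmrel: TmrelTable


def default_scenario(
    seed: int = 17,
    n_individuals: int = 2000,
    acceptability_level: str = "p99",
    **spec_overrides,
) -> Scenario:
    """Generate database, population, stats and compiled constraints."""
    from .food_model import filter_misreporters

    spec = GeneratorSpec(seed=seed, n_individuals=n_individuals, **spec_overrides)
    db = generate_food_db(spec)
    population = generate_population(spec, db)
    kept = filter_misreporters(population)
    stats = population_stats(kept, db)
    cs = compile_constraints(
        db, stats,
        nutrient_refs=default_nutrient_references(),
        fbdg=FbdgConfig(),
        acceptability=AcceptabilityConfig(level=acceptability_level),
        bioavailable_lower=default_bioavailable_lower(),
    )
    return Scenario(spec=spec, db=db, population=population, stats=stats,
                    constraints=cs, tmrel=tmrel_fixture(seed))


# ---------------------------------------------------------------------------
# Planted-optimum instances
# ---------------------------------------------------------------------------

def reference_feasible_diet(db: FoodDatabase) -> DietVector:
    """A guideline-compliant, nutrient-adequate diet built by construction.

    Quantities are chosen to satisfy every dietary-guideline rule with
    margin (two exact dairy portions, pulses and wholegrains above their
    floors, no sweet drinks, added-fat energy well under 16%) and to meet
    the default nutrient bounds with the archetype compositions.
    """
    grams = {
        "beef": 40.0, "poultry": 30.0, "lean_fish": 20.0, "fatty_fish": 20.0,
        "cheese": 30.0, "yogurt": 125.0,  # exactly 1 + 1 dairy portions
        "plant_substitutes": 150.0,
        "refined_bread": 60.0, "refined_pasta": 50.0,
        "wholegrain_bread": 90.0, "oats_muesli": 40.0, "wholegrain_pasta": 60.0,
        "potatoes": 50.0, "pulses": 100.0,
        "leafy_vegetables": 150.0, "root_vegetables": 100.0,
        "fruiting_vegetables": 150.0, "other_vegetables": 120.0,
        "temperate_fruit": 120.0, "citrus": 80.0, "tropical_fruit": 50.0,
        "fruit_juice": 100.0, "nuts": 25.0,
        "vegetable_oil": 20.0, "olive_oil": 10.0,
        "sweet_fat_foods": 40.0, "mixed_dishes": 30.0,
    }
    totals = np.zeros(db.n_groups)
    for name, q in grams.items():
        totals[db.group_index(name)] = q
    return DietVector.from_totals(totals)


@dataclass
class PlantedInstance:
    """A generated instance whose optimum is known in closed form."""

    db: FoodDatabase
    stats: PopulationStats
    constraints: ConstraintSet
    expected_diet: DietVector
    expected_td: float
    variant: str


def plant_known_optimum(
    spec: GeneratorSpec | None = None,
    target_diet: DietVector | None = None,
    variant: str = "A",
    binding_group: str = "beef",
    cap_fraction: float = 0.6,
) -> PlantedInstance:
    """Build an instance with a known departure-model optimum.

    Variant A sets the observed means equal to the target diet's totals
    and compiles the full constraint set, so TD = 0 is attainable at the
    (feasible) target and the model must recover it exactly.

    Variant B keeps a free observed diet and emits a single binding
    acceptability cap on one group at ``cap_fraction`` of its observed
    mean; the separable quadratic objective then has the closed-form
    optimum "observed mean, clipped to the cap on the capped group".
    """
    spec = spec or GeneratorSpec()
    db = generate_food_db(spec)
    if variant == "A":
        target = target_diet if target_diet is not None else reference_feasible_diet(db)
        totals = target.total
        sd = 0.25 * totals + 5.0
        p99 = 2.0 * totals + 200.0
        eer = diet_totals(target, db).energy_kcal
        mask = db.tag_mask("is_refined_cereal") | db.tag_mask("is_wholegrain")
        key = tuple(int(i) for i in np.flatnonzero(mask))
        stats = PopulationStats(
            mean=totals, sd=sd, p95=p99 * 0.9, p99=p99, energy_requirement=eer,
            coupling_caps={key: {"p95": totals[mask].sum() * 1.8,
                                 "p99": totals[mask].sum() * 2.0}},
        )
        cs = compile_constraints(
            db, stats,
            nutrient_refs=default_nutrient_references(),
            fbdg=FbdgConfig(),
            acceptability=AcceptabilityConfig(),
            bioavailable_lower=default_bioavailable_lower(),
        )
        violated = cs.violated(target.stacked(), tol=1e-9)
        if violated:
            raise ValueError(
                "planted target violates generated constraints: "
                + ", ".join(c.label for c in violated)
            )
        return PlantedInstance(db, stats, cs, target, 0.0, "A")
    if variant == "B":
        rng = np.random.default_rng(spec.seed + 2)
        mean = np.array([row[3] for row in _G], dtype=float)
        mean = mean * np.exp(rng.normal(0, 0.1, len(mean)))
        sd = 0.3 * mean + 2.0
        k = db.group_index(binding_group)
        cap = cap_fraction * mean[k]
        stats = PopulationStats(
            mean=mean, sd=sd, p95=mean * 10, p99=mean * 10 + 1,
            energy_requirement=2500.0,
        )
        from .constraints import LinearConstraint

        coeffs = np.zeros(2 * db.n_groups)
        coeffs[k] = coeffs[db.n_groups + k] = 1.0
        cs = ConstraintSet([LinearConstraint(
            coeffs, "<=", cap, "acceptability", f"cap_{binding_group}",
        )], db.n_groups)
        expected = mean.copy()
        expected[k] = cap
        td = ((cap - mean[k]) / sd[k]) ** 2
        return PlantedInstance(db, stats, cs, DietVector.from_totals(expected),
                               float(td), "B")
    raise ValueError(f"unknown variant {variant!r}")


def tmrel_fixture(seed: int = 0, jitter: float = 0.0) -> TmrelTable:
    """A small TMREL risk-factor table for the Health Risk Score.

    Target levels follow the Global Burden of Disease dietary risk-factor
    convention (g/d food-group targets plus a sodium target); an optional
    seeded jitter perturbs levels for property tests.
    """
    base = [
        # name, tmrel, max_deviation, direction, selector
        ("fruit", 250.0, 0.0, "protective-below", "is_fruit"),
        ("vegetables", 360.0, 0.0, "protective-below", "is_vegetable"),
        ("wholegrains", 145.0, 0.0, "protective-below", "is_wholegrain"),
        ("nuts_seeds", 21.0, 0.0, "protective-below", "is_nuts"),
        ("legumes", 60.0, 0.0, "protective-below", "is_pulse"),
        ("fish_seafood", 28.0, 0.0, "protective-below", "is_fish"),
        ("dairy", 435.0, 0.0, "protective-below", "is_dairy"),
        ("red_meat", 23.0, 200.0, "harmful-above", "is_red_meat"),
        ("processed_meat", 2.0, 100.0, "harmful-above", "is_processed_meat"),
        ("sugary_beverages", 3.0, 500.0, "harmful-above", "is_sweet_drink"),
        ("sodium", 2000.0, 6000.0, "harmful-above", "nutrient:sodium_mg"),
        ("fiber", 24.0, 2.0, "protective-below", "nutrient:fiber_g"),
    ]
    rng = np.random.default_rng(seed)
    factors = []
    for name, tmrel, maxdev, direction, selector in base:
        scale = float(np.exp(rng.normal(0, jitter))) if jitter > 0 else 1.0
        factors.append(RiskFactor(
            name=name, tmrel=tmrel * scale, max_deviation=maxdev * scale,
            direction=direction, selector=selector,
        ))
    return TmrelTable(factors)
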