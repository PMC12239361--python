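"""Per-diet indicator panel.

For every optimized (or observed) diet the panel reports environmental
pressures (GHGe, cumulative energy demand, land occupation), monetary
cost, the organic mass share, the plant share of protein, the emission
intensity per 1000 kcal, binary compliance with each dietary-guideline
rule, the departure from the observed diet, and a Health Risk Score (HRS).

The HRS summarizes long-term dietary health risk as the normalized mean
distance of risk-factor exposures from their theoretical minimum-risk
exposure levels (TMREL): 0% when every exposure meets its TMREL, 100%
when every exposure sits at (or beyond) its maximum-deviation reference
level.  It is a distance metric, not a disease-burden estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constraints import FbdgConfig, FbdgRule, default_fbdg_rules, DEFAULT_DAIRY_PORTIONS_G
from .food_model import DietVector, FoodDatabase, PopulationStats, diet_totals
from .optimizer import total_departure

__all__ = [
    "RiskFactor",
    "TmrelTable",
    "IndicatorPanel",
    "ghge_intensity",
    "organic_share",
    "plant_protein_share",
    "compute_hrs",
    "diet_exposures",
    "fbdg_compliance",
    "panel",
]


@dataclass(frozen=True)
class RiskFactor:
    """One dietary risk factor of the TMREL table.

    ``tmrel`` is the risk-minimizing exposure (g/d or nutrient unit);
    ``max_deviation`` the reference exposure at which the factor's risk
    contribution saturates; ``direction`` says whether risk accrues above
    the TMREL (``harmful-above``, e.g. red meat) or below it
    (``protective-below``, e.g. wholegrains).  ``selector`` maps the factor
    to a diet exposure: a tag / ``name:`` / ``category:`` selector summed
    by mass, or ``nutrient:<name>`` for a nutrient intake.
    """

    name: str
    tmrel: float
    max_deviation: float
    direction: str
    selector: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("harmful-above", "protective-below"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.max_deviation == self.tmrel:
            raise ValueError(f"{self.name}: max_deviation must differ from tmrel")
        if self.weight < 0:
            raise ValueError("risk-factor weight must be non-negative")


@dataclass
class TmrelTable:
    factors: list[RiskFactor]

    def __iter__(self):
        return iter(self.factors)

    def __len__(self) -> int:
        return len(self.factors)


@dataclass
class IndicatorPanel:
    """All Table-style indicators for one diet."""

    ghge: float  # kgCO2eq/d
    ced: float  # MJ/d
    lo: float  # m2/d
    cost: float  # EUR/d
    energy_kcal: float
    ghge_per_1000kcal: float
    organic_share: float  # %
    plant_protein_share: float  # %
    hrs: float  # %
    td: float
    fbdg_compliance: dict[str, bool]
    fbdg_satisfied: int = 0

    def __post_init__(self) -> None:
        self.fbdg_satisfied = sum(self.fbdg_compliance.values())

    def as_dict(self) -> dict:
        d = {
            "ghge_kgco2eq_d": self.ghge,
            "ced_mj_d": self.ced,
            "lo_m2_d": self.lo,
            "cost_eur_d": self.cost,
            "energy_kcal_d": self.energy_kcal,
            "ghge_per_1000kcal": self.ghge_per_1000kcal,
            "organic_share_pct": self.organic_share,
            "plant_protein_share_pct": self.plant_protein_share,
            "hrs_pct": self.hrs,
            "td": self.td,
            "fbdg_satisfied": self.fbdg_satisfied,
        }
        d.update({f"fbdg_{k}": bool(v) for k, v in self.fbdg_compliance.items()})
        return d


def ghge_intensity(ghge: float, energy_kcal: float) -> float:
    """Emission intensity, kgCO2eq per 1000 kcal."""
    if energy_kcal <= 0:
        raise ValueError("energy must be positive")
    return 1000.0 * ghge / energy_kcal


def organic_share(diet: DietVector) -> float:
    """Mass share of organically produced food in the diet, %."""
    total = float(diet.total.sum())
    if total <= 0:
        raise ValueError("diet has zero total mass")
    return 100.0 * float(diet.q_org.sum()) / total


def plant_protein_share(diet: DietVector, db: FoodDatabase) -> float:
    """Plant-sourced share of total protein intake, %."""
    totals = diet_totals(diet, db)
    if totals.protein_g <= 0:
        raise ValueError("diet has zero protein")
    return 100.0 * totals.plant_protein_g / totals.protein_g


def diet_exposures(diet: DietVector, db: FoodDatabase, tmrel: TmrelTable) -> dict[str, float]:
    """Map a diet onto the risk-factor exposures of a TMREL table."""
    out: dict[str, float] = {}
    totals = None
    for rf in tmrel:
        if rf.selector.startswith("nutrient:"):
            if totals is None:
                totals = diet_totals(diet, db)
            key = rf.selector.split(":", 1)[1]
            if key not in totals.nutrients:
                raise KeyError(f"risk factor {rf.name!r}: unknown nutrient {key!r}")
            out[rf.name] = totals.nutrients[key]
        else:
            mask = db.tag_mask(rf.selector)
            out[rf.name] = float(diet.total[mask].sum())
    return out


def compute_hrs(
    exposures: Mapping[str, float],
    tmrel: TmrelTable,
) -> float:
    """Health Risk Score: normalized mean distance to the TMRELs, in %.

    Each factor contributes ``clip01(|exposure - tmrel| / |max_dev - tmrel|)``
    counted only on its risky side (excess for harmful-above factors,
    shortfall for protective-below ones); the HRS is 100 x the
    weighted mean of these contributions.  Exactly 0 when every exposure
    meets its TMREL and exactly 100 when every exposure is at or beyond its
    maximum-deviation level.
    """
    if len(tmrel) == 0:
        raise ValueError("empty TMREL table")
    contributions, weights = [], []
    for rf in tmrel:
        if rf.name not in exposures:
            raise KeyError(f"no exposure mapped for risk factor {rf.name!r}")
        x = exposures[rf.name]
        if rf.direction == "harmful-above":
            dev = max(0.0, x - rf.tmrel)
        else:
            dev = max(0.0, rf.tmrel - x)
        norm = abs(rf.max_deviation - rf.tmrel)
        contributions.append(min(1.0, dev / norm))
        weights.append(rf.weight)
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("risk-factor weights sum to zero")
    return float(100.0 * np.average(np.asarray(contributions), weights=w))


def fbdg_compliance(
    diet: DietVector,
    db: FoodDatabase,
    rules: Sequence[FbdgRule] | None = None,
    portion_table: Mapping[str, float] | None = None,
    tol: float = 1e-6,
) -> dict[str, bool]:
    """Direct rule-by-rule guideline compliance check.

    Independent of the constraint compiler: evaluates each rule on the
    diet itself, with the juice credit as a true ``min()`` and the
    added-fat rule as a true energy ratio (not the linearization), so it
    can serve as a cross-check on optimizer output.
    """
    rules = list(rules) if rules is not None else default_fbdg_rules()
    portions = dict(DEFAULT_DAIRY_PORTIONS_G)
    if portion_table:
        portions.update(portion_table)
    t = diet.total
    out: dict[str, bool] = {}

    def mass(tags: Sequence[str]) -> float:
        m = np.zeros(db.n_groups, dtype=bool)
        for tag in tags:
            m |= db.tag_mask(tag)
        return float(t[m].sum())

    for rule in rules:
        if rule.kind == "mass_sum":
            v = mass(rule.tags)
            ok = v >= rule.threshold - tol if rule.sense == ">=" else v <= rule.threshold + tol
        elif rule.kind == "zero":
            ok = mass(rule.tags) <= tol
        elif rule.kind == "fruit_veg_credit":
            fv = mass(("is_fruit", "is_vegetable"))
            juice = mass(("is_fruit_juice",))
            credit = min(juice, float(rule.params.get("juice_portion_g", 150.0)))
            ok = fv + credit >= rule.threshold - tol
        elif rule.kind == "dairy_portions":
            count = 0.0
            for i in np.flatnonzero(db.tag_mask("is_dairy")):
                count += t[i] / portions[db.groups[i].name]
            band = float(rule.params.get("band", 0.0))
            ok = abs(count - rule.threshold) <= band + tol
        elif rule.kind == "added_fat_energy":
            totals = diet_totals(diet, db)
            e_per_g = db.nutrient_per_gram("energy_kcal")
            m = db.tag_mask("is_added_fat")
            q = np.stack([diet.q_conv, diet.q_org], axis=1)
            fat_energy = float((q[m] * e_per_g[m]).sum())
            ok = (totals.energy_kcal > 0
                  and fat_energy / totals.energy_kcal <= rule.threshold + tol)
        else:
            raise ValueError(f"unknown rule kind {rule.kind!r}")
        out[rule.rule_id] = bool(ok)
    return out


def panel(
    diet: DietVector,
    db: FoodDatabase,
    stats: PopulationStats,
    tmrel: TmrelTable,
    rules: Sequence[FbdgRule] | None = None,
    fbdg_config: FbdgConfig | None = None,
) -> IndicatorPanel:
    """Assemble the full indicator panel for one diet."""
    totals = diet_totals(diet, db)
    exposures = diet_exposures(diet, db, tmrel)
    if rules is None:
        rules = default_fbdg_rules(fbdg_config)
    portion_table = fbdg_config.dairy_portion_sizes if fbdg_config else None
    return IndicatorPanel(
        ghge=totals.ghge,
        ced=totals.ced,
        lo=totals.lo,
        cost=totals.cost,
        energy_kcal=totals.energy_kcal,
        ghge_per_1000kcal=ghge_intensity(totals.ghge, totals.energy_kcal),
        organic_share=organic_share(diet),
        plant_protein_share=plant_protein_share(diet, db),
        hrs=compute_hrs(exposures, tmrel),
        td=total_departure(diet, stats),
        fbdg_compliance=fbdg_compliance(diet, db, rules, portion_table),
    )
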