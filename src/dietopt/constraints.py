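"""Compilation of nutrient, dietary-guideline and acceptability constraints.

All constraints are linear (or linearized, e.g. the added-fat energy-share
rule) in the stacked decision vector ``[q_conv; q_org]`` of length 2G, so
that the departure-minimization model is a convex QP and the emission
extremum models are LPs.

Constraint families, by provenance tag:

``energy``
    total energy within +/-8% of the population energy requirement;
``nutrient``
    lower/upper bounds on nutrient intakes, blended across male/female
    reference strata, with bioavailability-adjusted lower bounds for iron
    and zinc;
``fbdg``
    the twelve quantitative food-based dietary-guideline rules;
``acceptability``/``coupling``
    per-group caps at a high percentile (P99, or P95 in sensitivity runs)
    of the observed weighted consumption, with an exemption list (pulses)
    and coupled caps on substitutable group sets (refined + wholegrain
    cereals);
``ghge_target``
    the emission equality added per grid-scan level (by the optimizer).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .food_model import DietVector, FoodDatabase, PopulationStats, diet_totals

__all__ = [
    "LinearConstraint",
    "ConstraintSet",
    "NutrientReference",
    "FbdgRule",
    "FbdgConfig",
    "AcceptabilityConfig",
    "BioavailabilityParams",
    "blend_reference_values",
    "energy_band",
    "weekly_to_daily",
    "format_daily_bound",
    "default_fbdg_rules",
    "build_fbdg_constraints",
    "added_fat_energy_constraint",
    "build_acceptability",
    "register_bioavailability_model",
    "apply_bioavailability",
    "compile_constraints",
]

PROVENANCES = (
    "nutrient",
    "energy",
    "fbdg",
    "acceptability",
    "coupling",
    "ghge_target",
    "meat_cap",
)

#: Dairy portion sizes in grams (one "portion" of each dairy group).
DEFAULT_DAIRY_PORTIONS_G: dict[str, float] = {
    "milk": 150.0,
    "cheese": 30.0,
    "yogurt": 125.0,
    "petits_suisses": 120.0,
    "cottage_cheese": 100.0,
}


@dataclass
class LinearConstraint:
    """One linear bound ``coeffs @ x (sense) rhs`` on the stacked diet vector."""

    coeffs: np.ndarray  # length 2G: [conv block, org block]
    sense: str  # "<=", ">=", "=="
    rhs: float
    provenance: str
    label: str
    unit: str = "g/d"

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.sense not in ("<=", ">=", "=="):
            raise ValueError(f"invalid sense {self.sense!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"invalid provenance {self.provenance!r}")
        if not np.any(self.coeffs != 0):
            raise ValueError(f"constraint {self.label!r} has all-zero coefficients")
        if not np.isfinite(self.rhs):
            raise ValueError(f"constraint {self.label!r} has non-finite rhs")

    def value(self, x: np.ndarray) -> float:
        return float(self.coeffs @ x)

    def residual(self, x: np.ndarray) -> float:
        """Signed violation (positive = violated) of the constraint at x."""
        v = self.value(x)
        if self.sense == "<=":
            return v - self.rhs
        if self.sense == ">=":
            return self.rhs - v
        return abs(v - self.rhs)


@dataclass
class ConstraintSet:
    """A compiled list of linear constraints over a fixed food database."""

    constraints: list[LinearConstraint]
    n_groups: int

    def __iter__(self):
        return iter(self.constraints)

    def __len__(self) -> int:
        return len(self.constraints)

    def add(self, con: LinearConstraint) -> None:
        if con.coeffs.shape != (2 * self.n_groups,):
            raise ValueError("constraint dimension mismatch")
        self.constraints.append(con)

    def extended(self, extra: Iterable[LinearConstraint]) -> "ConstraintSet":
        new = ConstraintSet(list(self.constraints), self.n_groups)
        for con in extra:
            new.add(con)
        return new

    def matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(A_ub, b_ub, A_eq, b_eq)`` with >= rows negated into <=."""
        a_ub, b_ub, a_eq, b_eq = [], [], [], []
        for con in self.constraints:
            if con.sense == "<=":
                a_ub.append(con.coeffs)
                b_ub.append(con.rhs)
            elif con.sense == ">=":
                a_ub.append(-con.coeffs)
                b_ub.append(-con.rhs)
            else:
                a_eq.append(con.coeffs)
                b_eq.append(con.rhs)
        n = 2 * self.n_groups
        A_ub = np.array(a_ub) if a_ub else np.zeros((0, n))
        A_eq = np.array(a_eq) if a_eq else np.zeros((0, n))
        return A_ub, np.array(b_ub), A_eq, np.array(b_eq)

    def residuals(self, x: np.ndarray) -> np.ndarray:
        return np.array([con.residual(x) for con in self.constraints])

    def violated(self, x: np.ndarray, tol: float = 1e-6) -> list[LinearConstraint]:
        """Constraints violated at x beyond a relative feasibility tolerance."""
        out = []
        for con in self.constraints:
            scale = max(1.0, abs(con.rhs))
            if con.residual(x) > tol * scale:
                out.append(con)
        return out

    def audit_table(self) -> pd.DataFrame:
        """Human-readable audit table (label, sense, rhs, provenance, unit)."""
        return pd.DataFrame(
            {
                "label": [c.label for c in self.constraints],
                "sense": [c.sense for c in self.constraints],
                "rhs": [c.rhs for c in self.constraints],
                "unit": [c.unit for c in self.constraints],
                "provenance": [c.provenance for c in self.constraints],
            }
        )


@dataclass(frozen=True)
class NutrientReference:
    """Lower/upper reference bounds for one nutrient (``None`` = unbounded)."""

    nutrient: str
    lower: float | None = None
    upper: float | None = None
    unit: str = "per day"

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError(
                f"{self.nutrient}: lower bound {self.lower} exceeds upper {self.upper}"
            )


def blend_reference_values(
    strata_refs: Mapping[str, NutrientReference],
    strata_weights: Mapping[str, float],
    tol: float = 1e-9,
) -> NutrientReference:
    """Blend per-stratum reference values into one average-individual bound.

    The blended bound on each side is the weighted average of the stratum
    bounds (weights over e.g. males, females with high iron requirements,
    and females with low/moderate iron requirements must sum to 1).  A side
    is kept unbounded only if it is unbounded in every stratum.
    """
    if set(strata_refs) != set(strata_weights):
        raise ValueError("strata_refs and strata_weights must share keys")
    weights = {k: float(v) for k, v in strata_weights.items()}
    if any(w < 0 for w in weights.values()):
        raise ValueError("strata weights must be non-negative")
    if abs(sum(weights.values()) - 1.0) > tol:
        raise ValueError(f"strata weights must sum to 1, got {sum(weights.values())}")
    nutrients = {r.nutrient for r in strata_refs.values()}
    if len(nutrients) != 1:
        raise ValueError("all strata must reference the same nutrient")
    units = {r.unit for r in strata_refs.values()}
    if len(units) != 1:
        raise ValueError("all strata must share the unit")

    def blend(side: str) -> float | None:
        vals = {k: getattr(r, side) for k, r in strata_refs.items()}
        finite = {k: v for k, v in vals.items() if v is not None}
        if not finite:
            return None
        if len(finite) != len(vals):
            raise ValueError(
                f"{side} bound defined in some strata but not others; "
                "cannot blend a partially unbounded side"
            )
        return sum(weights[k] * v for k, v in finite.items())

    return NutrientReference(
        nutrient=next(iter(nutrients)),
        lower=blend("lower"),
        upper=blend("upper"),
        unit=next(iter(units)),
    )


def energy_band(
    eer: float, db: FoodDatabase, relative_width: float = 0.08
) -> tuple[LinearConstraint, LinearConstraint]:
    """Energy-intake band: total energy within +/-8% of the requirement."""
    if eer <= 0:
        raise ValueError("energy requirement must be positive")
    coeffs = np.concatenate(
        [db.nutrient_per_gram("energy_kcal")[:, 0], db.nutrient_per_gram("energy_kcal")[:, 1]]
    )
    lo = LinearConstraint(
        coeffs=coeffs, sense=">=", rhs=(1 - relative_width) * eer,
        provenance="energy", label="energy_lower", unit="kcal/d",
    )
    hi = LinearConstraint(
        coeffs=coeffs, sense="<=", rhs=(1 + relative_width) * eer,
        provenance="energy", label="energy_upper", unit="kcal/d",
    )
    return lo, hi


def weekly_to_daily(grams_per_week: float) -> float:
    """Convert a weekly guideline quantity to an exact daily one (g/wk -> g/d)."""
    if grams_per_week < 0:
        raise ValueError("weekly quantity must be non-negative")
    return grams_per_week / 7.0


def format_daily_bound(grams_per_week: float, decimals: int = 1) -> float:
    """Daily bound rounded to the precision a guideline table prints it at.

    Display only — compiled constraints always use the unrounded value.
    """
    return round(weekly_to_daily(grams_per_week), decimals)


@dataclass(frozen=True)
class FbdgRule:
    """One quantitative dietary-guideline rule.

    ``kind`` selects how the rule maps to coefficients:

    - ``mass_sum``: bound on total g/d over the tagged groups;
    - ``fruit_veg_credit``: fruit+vegetable floor where fruit juice counts
      up to one portion;
    - ``dairy_portions``: portion-count constraint over dairy groups;
    - ``added_fat_energy``: added-fat energy share cap (linearized);
    - ``zero``: equality to zero over the tagged groups.
    """

    rule_id: str
    kind: str
    tags: tuple[str, ...] = ()
    sense: str = ">="
    threshold: float = 0.0
    params: Mapping[str, float] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError(f"rule {self.rule_id}: threshold must be non-negative")


@dataclass
class FbdgConfig:
    """Thresholds of the twelve guideline rules (main-scenario defaults).

    The nuts floor defaults to 15 g/d (the level every published compliant
    model diet sits at) with the 30 g/d guideline wording available by
    config.  The red-meat cap is the 500 g/wk main scenario.  The fatty-fish
    floor uses the guideline table's printed daily value (one 100 g portion
    per week).
    """

    fruit_veg_min_g: float = 400.0
    juice_portion_g: float = 150.0
    juice_max_g: float = 150.0
    nuts_min_g: float = 15.0
    pulses_min_g_wk: float = 400.0
    dairy_portions: float = 2.0
    dairy_portion_band: float = 0.0  # half-width of allowed band around the target
    dairy_portion_sizes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DAIRY_PORTIONS_G)
    )
    wholegrain_min_g_wk: float = 400.0
    red_meat_max_g_wk: float = 500.0
    processed_meat_max_g_wk: float = 150.0
    seafood_min_g_wk: float = 200.0
    fatty_fish_min_g_wk: float = 100.0
    added_fat_energy_frac_max: float = 0.16
    sweet_drinks_zero: bool = True
    alcohol_max_g: float | None = None  # optional, off by default


def default_fbdg_rules(config: FbdgConfig | None = None) -> list[FbdgRule]:
    """The guideline rule set at the configured thresholds."""
    c = config or FbdgConfig()
    rules = [
        FbdgRule("fruit_veg_min", "fruit_veg_credit",
                 ("is_fruit", "is_vegetable", "is_fruit_juice"), ">=",
                 c.fruit_veg_min_g, {"juice_portion_g": c.juice_portion_g},
                 "fruit+vegetables with juice credited up to one portion"),
        FbdgRule("juice_max", "mass_sum", ("is_fruit_juice",), "<=", c.juice_max_g),
        FbdgRule("nuts_min", "mass_sum", ("is_nuts",), ">=", c.nuts_min_g),
        FbdgRule("pulses_min", "mass_sum", ("is_pulse",), ">=",
                 weekly_to_daily(c.pulses_min_g_wk)),
        FbdgRule("dairy_portions", "dairy_portions", ("is_dairy",), "==",
                 c.dairy_portions,
                 {"band": c.dairy_portion_band},
                 "portion count over dairy groups"),
        FbdgRule("wholegrain_min", "mass_sum", ("is_wholegrain",), ">=",
                 weekly_to_daily(c.wholegrain_min_g_wk)),
        FbdgRule("red_meat_max", "mass_sum", ("is_red_meat",), "<=",
                 weekly_to_daily(c.red_meat_max_g_wk)),
        FbdgRule("processed_meat_max", "mass_sum", ("is_processed_meat",), "<=",
                 weekly_to_daily(c.processed_meat_max_g_wk)),
        FbdgRule("seafood_min", "mass_sum", ("is_fish",), ">=",
                 weekly_to_daily(c.seafood_min_g_wk)),
        FbdgRule("fatty_fish_min", "mass_sum", ("is_fatty_fish",), ">=",
                 weekly_to_daily(c.fatty_fish_min_g_wk)),
        FbdgRule("added_fat_energy", "added_fat_energy", ("is_added_fat",), "<=",
                 c.added_fat_energy_frac_max),
    ]
    if c.sweet_drinks_zero:
        rules.append(FbdgRule("sweet_drinks_zero", "zero", ("is_sweet_drink",), "==", 0.0))
    if c.alcohol_max_g is not None:
        rules.append(FbdgRule("alcohol_max", "mass_sum", ("name:alcoholic_beverages",),
                              "<=", c.alcohol_max_g))
    return rules


def _mass_coeffs(db: FoodDatabase, tags: Sequence[str]) -> np.ndarray:
    mask = np.zeros(db.n_groups, dtype=bool)
    for tag in tags:
        mask |= db.tag_mask(tag)
    if not mask.any():
        raise ValueError(f"tags {tags} match no food group")
    return np.concatenate([mask.astype(float), mask.astype(float)])


def added_fat_energy_constraint(
    db: FoodDatabase, frac_max: float = 0.16
) -> LinearConstraint:
    """Added-fat energy share cap, linearized.

    The rule "energy from added fats <= frac_max of total energy" is a
    ratio; it is compiled as the equivalent linear constraint
    ``sum_addedfat e_i q_i - frac_max * sum_all e_i q_i <= 0``, exact
    whenever total energy is positive (guaranteed by the energy band).
    """
    e = db.nutrient_per_gram("energy_kcal")  # (G, 2)
    mask = db.tag_mask("is_added_fat")
    if not mask.any():
        raise ValueError("no group tagged is_added_fat")
    coeffs = np.concatenate([e[:, 0] * mask, e[:, 1] * mask]) - frac_max * np.concatenate(
        [e[:, 0], e[:, 1]]
    )
    return LinearConstraint(
        coeffs=coeffs, sense="<=", rhs=0.0, provenance="fbdg",
        label="added_fat_energy_share", unit="kcal/d",
    )


def build_fbdg_constraints(
    rules: Sequence[FbdgRule],
    db: FoodDatabase,
    portion_table: Mapping[str, float] | None = None,
) -> list[LinearConstraint]:
    """Compile guideline rules to linear constraints on the diet vector.

    The fruit&vegetable floor with capped juice credit
    ``F + V + min(J, portion) >= t`` is compiled exactly as the pair of
    linear constraints ``F + V + J >= t`` and ``F + V >= t - portion``
    (``min(a, b) >= c`` iff ``a >= c`` and ``b >= c``).
    """
    out: list[LinearConstraint] = []
    for rule in rules:
        if rule.kind == "mass_sum":
            out.append(LinearConstraint(
                coeffs=_mass_coeffs(db, rule.tags), sense=rule.sense,
                rhs=rule.threshold, provenance="fbdg", label=rule.rule_id,
            ))
        elif rule.kind == "zero":
            out.append(LinearConstraint(
                coeffs=_mass_coeffs(db, rule.tags), sense="==", rhs=0.0,
                provenance="fbdg", label=rule.rule_id,
            ))
        elif rule.kind == "fruit_veg_credit":
            fv = _mass_coeffs(db, ("is_fruit", "is_vegetable"))
            juice = _mass_coeffs(db, ("is_fruit_juice",))
            portion = float(rule.params.get("juice_portion_g", 150.0))
            out.append(LinearConstraint(
                coeffs=fv + juice, sense=">=", rhs=rule.threshold,
                provenance="fbdg", label=f"{rule.rule_id}_with_juice",
            ))
            out.append(LinearConstraint(
                coeffs=fv, sense=">=", rhs=rule.threshold - portion,
                provenance="fbdg", label=f"{rule.rule_id}_juice_capped",
            ))
        elif rule.kind == "dairy_portions":
            portions = dict(DEFAULT_DAIRY_PORTIONS_G)
            if portion_table:
                portions.update(portion_table)
            mask = db.tag_mask("is_dairy")
            if not mask.any():
                raise ValueError("no group tagged is_dairy")
            per_g = np.zeros(db.n_groups)
            for i in np.flatnonzero(mask):
                name = db.groups[i].name
                if name not in portions:
                    raise ValueError(f"no portion size for dairy group {name!r}")
                per_g[i] = 1.0 / portions[name]
            coeffs = np.concatenate([per_g, per_g])
            band = float(rule.params.get("band", 0.0))
            if band > 0:
                out.append(LinearConstraint(coeffs, ">=", rule.threshold - band,
                                            "fbdg", f"{rule.rule_id}_lower", "portions/d"))
                out.append(LinearConstraint(coeffs, "<=", rule.threshold + band,
                                            "fbdg", f"{rule.rule_id}_upper", "portions/d"))
            else:
                out.append(LinearConstraint(coeffs, "==", rule.threshold,
                                            "fbdg", rule.rule_id, "portions/d"))
        elif rule.kind == "added_fat_energy":
            out.append(added_fat_energy_constraint(db, rule.threshold))
        else:
            raise ValueError(f"unknown rule kind {rule.kind!r}")
    return out


@dataclass
class AcceptabilityConfig:
    """Acceptability-cap settings: percentile level, coupling and exemptions."""

    level: str = "p99"  # or "p95"
    coupling_tags: tuple[tuple[str, ...], ...] = (("is_refined_cereal", "is_wholegrain"),)
    exempt_tags: tuple[str, ...] = ("is_pulse",)


def build_acceptability(
    stats: PopulationStats,
    level: str = "p99",
    coupling: Iterable[Sequence[int]] = (),
    exempt: Iterable[int] = (),
    db: FoodDatabase | None = None,
) -> list[LinearConstraint]:
    """Per-group upper caps at a high percentile of observed consumption.

    Exempt groups get no cap (their observed intake is too low to anchor a
    meaningful ceiling — pulses in the main scenario).  Each coupled set is
    capped only on its *sum*, at the percentile of the summed consumption
    when available in ``stats.coupling_caps`` (fallback: the sum of
    per-group percentiles, a looser cap), so members may individually
    exceed their own percentile.  No lower acceptability bounds exist.
    """
    caps = stats.percentile(level)
    exempt_set = {int(i) for i in exempt}
    coupled_sets = [tuple(sorted(int(i) for i in s)) for s in coupling]
    coupled_members: set[int] = set()
    for s in coupled_sets:
        coupled_members.update(s)
    overlap = coupled_members & exempt_set
    if overlap:
        raise ValueError(f"coupled groups {sorted(overlap)} overlap the exemption list")
    g = stats.n_groups
    names = [db.groups[i].name if db is not None else f"group{i}" for i in range(g)]
    out: list[LinearConstraint] = []
    for i in range(g):
        if i in exempt_set or i in coupled_members:
            continue
        coeffs = np.zeros(2 * g)
        coeffs[i] = coeffs[g + i] = 1.0
        out.append(LinearConstraint(
            coeffs=coeffs, sense="<=", rhs=float(caps[i]),
            provenance="acceptability", label=f"acceptability_{level}_{names[i]}",
        ))
    for s in coupled_sets:
        coeffs = np.zeros(2 * g)
        for i in s:
            coeffs[i] = coeffs[g + i] = 1.0
        if s in stats.coupling_caps:
            rhs = float(stats.coupling_caps[s][level])
        else:
            rhs = float(sum(caps[i] for i in s))
        out.append(LinearConstraint(
            coeffs=coeffs, sense="<=", rhs=rhs, provenance="coupling",
            label=f"acceptability_{level}_coupled_" + "+".join(names[i] for i in s),
        ))
    return out


# --------------------------------------------------------------------------
# Iron/zinc bioavailability: pluggable absorption models
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BioavailabilityParams:
    """Coefficients of the parametric absorption model.

    Absorption of non-heme iron and zinc depends on the meal matrix:
    ascorbic acid enhances and phytate-rich fiber inhibits uptake.  The
    default model modulates a base fraction by saturating enhancer and
    inhibitor terms computed from whole-diet aggregates:

    ``f = clip(base * (1 + a_enh * E / (E + e_half)) / (1 + a_inh * I / i_half),
    f_min, f_max)``

    with ``E`` the vitamin C intake (mg/d) and ``I`` the fiber intake (g/d,
    phytate proxy).
    """

    iron_base: float = 0.10
    zinc_base: float = 0.25
    a_enh: float = 0.5
    e_half: float = 100.0  # mg/d vitamin C at half-maximal enhancement
    a_inh: float = 0.5
    i_half: float = 50.0  # g/d fiber scale for inhibition
    f_min: float = 0.03
    f_max: float = 0.35


BioavailabilityModel = Callable[[DietVector, FoodDatabase, BioavailabilityParams],
                                dict[str, float]]

_BIOAVAILABILITY_MODELS: dict[str, BioavailabilityModel] = {}


def register_bioavailability_model(name: str, model: BioavailabilityModel) -> None:
    _BIOAVAILABILITY_MODELS[name] = model


def _parametric_fractions(
    diet: DietVector, db: FoodDatabase, params: BioavailabilityParams
) -> dict[str, float]:
    totals = diet_totals(diet, db)
    e = totals.nutrients.get("vitamin_c_mg", 0.0)
    i = totals.nutrients.get("fiber_g", 0.0)
    modulation = (1 + params.a_enh * e / (e + params.e_half)) / (
        1 + params.a_inh * i / params.i_half
    )
    return {
        "iron": float(np.clip(params.iron_base * modulation, params.f_min, params.f_max)),
        "zinc": float(np.clip(params.zinc_base * modulation, params.f_min, params.f_max)),
    }


def _constant_fractions(
    diet: DietVector, db: FoodDatabase, params: BioavailabilityParams
) -> dict[str, float]:
    return {"iron": params.iron_base, "zinc": params.zinc_base}


register_bioavailability_model("parametric", _parametric_fractions)
register_bioavailability_model("constant", _constant_fractions)


def apply_bioavailability(
    model: str,
    diet: DietVector,
    db: FoodDatabase,
    params: BioavailabilityParams | None = None,
) -> tuple[float, float]:
    """Availability-adjusted (absorbable) iron and zinc intakes, mg/d."""
    if model not in _BIOAVAILABILITY_MODELS:
        raise KeyError(
            f"unregistered bioavailability model {model!r}; "
            f"known: {sorted(_BIOAVAILABILITY_MODELS)}"
        )
    params = params or BioavailabilityParams()
    fracs = _BIOAVAILABILITY_MODELS[model](diet, db, params)
    totals = diet_totals(diet, db)
    iron = totals.nutrients.get("iron_mg", 0.0)
    zinc = totals.nutrients.get("zinc_mg", 0.0)
    return fracs["iron"] * iron, fracs["zinc"] * zinc


# --------------------------------------------------------------------------
# Full compilation
# --------------------------------------------------------------------------

def _nutrient_coeffs(db: FoodDatabase, nutrient: str) -> np.ndarray:
    per_g = db.nutrient_per_gram(nutrient)
    return np.concatenate([per_g[:, 0], per_g[:, 1]])


def compile_constraints(
    db: FoodDatabase,
    stats: PopulationStats,
    nutrient_refs: Sequence[NutrientReference] = (),
    fbdg: FbdgConfig | None = None,
    acceptability: AcceptabilityConfig | None = None,
    bioavailability_model: str = "parametric",
    bioavailability_params: BioavailabilityParams | None = None,
    bioavailable_lower: Mapping[str, float] | None = None,
) -> ConstraintSet:
    """Compile the full main-scenario constraint set.

    ``nutrient_refs`` are already-blended reference bounds per nutrient;
    iron/zinc lower bounds in ``bioavailable_lower`` (mg/d of *absorbable*
    mineral, deficiency-prevalence derived) are compiled with the absorption
    fraction of the configured model evaluated at the observed-mean diet, so
    the constraint stays linear in the decision vector.
    """
    cs = ConstraintSet([], db.n_groups)
    lo, hi = energy_band(stats.energy_requirement, db)
    cs.add(lo)
    cs.add(hi)
    for ref in nutrient_refs:
        coeffs = _nutrient_coeffs(db, ref.nutrient)
        if ref.lower is not None:
            cs.add(LinearConstraint(coeffs, ">=", ref.lower, "nutrient",
                                    f"{ref.nutrient}_lower", ref.unit))
        if ref.upper is not None:
            cs.add(LinearConstraint(coeffs, "<=", ref.upper, "nutrient",
                                    f"{ref.nutrient}_upper", ref.unit))
    if bioavailable_lower:
        obs_diet = DietVector.from_totals(stats.mean)
        params = bioavailability_params or BioavailabilityParams()
        fracs = _BIOAVAILABILITY_MODELS[bioavailability_model](obs_diet, db, params)
        col = {"iron": "iron_mg", "zinc": "zinc_mg"}
        for mineral, bound in bioavailable_lower.items():
            coeffs = _nutrient_coeffs(db, col[mineral]) * fracs[mineral]
            cs.add(LinearConstraint(coeffs, ">=", float(bound), "nutrient",
                                    f"bioavailable_{mineral}_lower", "mg/d"))
    fbdg = fbdg or FbdgConfig()
    for con in build_fbdg_constraints(default_fbdg_rules(fbdg), db,
                                      fbdg.dairy_portion_sizes):
        cs.add(con)
    acc = acceptability or AcceptabilityConfig()
    coupling_sets = []
    for tag_set in acc.coupling_tags:
        mask = np.zeros(db.n_groups, dtype=bool)
        for tag in tag_set:
            mask |= db.tag_mask(tag)
        coupling_sets.append(tuple(np.flatnonzero(mask)))
    exempt: set[int] = set()
    for tag in acc.exempt_tags:
        exempt.update(np.flatnonzero(db.tag_mask(tag)))
    for con in build_acceptability(stats, acc.level, coupling_sets, exempt, db):
        cs.add(con)
    return cs
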