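"""Domain types for foods, diets and populations.

The diet-optimization pipeline works on *food groups* (47 in the default
scenario), each available in two production modes (conventional and
organic).  A diet is a vector of daily consumed grams per group and mode;
nutrient intakes, environmental pressures (greenhouse-gas emissions,
cumulative energy demand, land occupation) and monetary cost are all
linear aggregates of that vector.

Population-level inputs are weighted consumption statistics (mean, SD and
high percentiles per group) derived from individual food-frequency data,
after removing energy misreporters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "MODES",
    "TAG_NAMES",
    "CATEGORIES",
    "FoodGroup",
    "FoodDatabase",
    "PopulationStats",
    "DietVector",
    "DietTotals",
    "Individual",
    "ORGANIC_FREQUENCY_WEIGHTS",
    "weight_organic_frequency",
    "filter_misreporters",
    "weighted_percentile",
    "aggregate_population_stats",
    "diet_totals",
]

#: Production modes, in storage order (axis 1 of every per-mode array).
MODES: tuple[str, str] = ("conventional", "organic")

CATEGORIES = ("animal", "plant", "mixed", "beverage", "fat", "other")

#: Boolean tags that drive membership in food-based dietary-guideline rules.
TAG_NAMES = (
    "is_pulse",
    "is_refined_cereal",
    "is_wholegrain",
    "is_red_meat",
    "is_processed_meat",
    "is_poultry",
    "is_dairy",
    "is_fish",
    "is_fatty_fish",
    "is_fruit",
    "is_vegetable",
    "is_fruit_juice",
    "is_nuts",
    "is_added_fat",
    "is_sweet_drink",
)

#: Five-point organic-consumption frequency scale and its mass-fraction weights.
ORGANIC_FREQUENCY_WEIGHTS: dict[str, float] = {
    "never": 0.0,
    "rarely": 0.25,
    "half-of-time": 0.5,
    "often": 0.75,
    "always": 1.0,
}

# Energy-intake / energy-requirement band outside which an individual is
# classified as an energy misreporter (1st/99th percentile cut-offs of the
# ratio distribution in the source cohort).
MISREPORTER_LOW = 0.35
MISREPORTER_HIGH = 1.93


@dataclass(frozen=True)
class FoodGroup:
    """One optimization food group and the guideline tags attached to it."""

    id: int
    name: str
    category: Literal["animal", "plant", "mixed", "beverage", "fat", "other"]
    is_pulse: bool = False
    is_refined_cereal: bool = False
    is_wholegrain: bool = False
    is_red_meat: bool = False
    is_processed_meat: bool = False
    is_poultry: bool = False
    is_dairy: bool = False
    is_fish: bool = False
    is_fatty_fish: bool = False
    is_fruit: bool = False
    is_vegetable: bool = False
    is_fruit_juice: bool = False
    is_nuts: bool = False
    is_added_fat: bool = False
    is_sweet_drink: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.is_refined_cereal and self.is_wholegrain:
            raise ValueError(
                f"group {self.name!r}: is_refined_cereal and is_wholegrain are exclusive"
            )

    def has_tag(self, tag: str) -> bool:
        if tag not in TAG_NAMES:
            raise KeyError(f"unknown tag {tag!r}")
        return bool(getattr(self, tag))


@dataclass
class FoodDatabase:
    """Per-group, per-mode nutrient densities, footprints and prices.

    Arrays are indexed ``[group, mode]`` with mode order :data:`MODES`.
    Nutrient densities are stored per 100 g (the unit composition tables
    use); every aggregation converts to per-gram exactly once, in
    :func:`diet_totals`.

    Attributes
    ----------
    groups
        The food groups, ordered by ``id`` = positional index.
    nutrients
        Nutrient column names; must contain ``energy_kcal`` and ``protein_g``.
    density
        ``(G, 2, K)`` nutrient content per 100 g.
    ghge, ced, lo, price
        ``(G, 2)`` footprints per kg: kgCO2eq, MJ, m2, EUR.
    plant_protein_frac
        ``(G,)`` fraction of each group's protein that is plant-sourced.
    """

    groups: list[FoodGroup]
    nutrients: list[str]
    density: np.ndarray
    ghge: np.ndarray
    ced: np.ndarray
    lo: np.ndarray
    price: np.ndarray
    plant_protein_frac: np.ndarray

    def __post_init__(self) -> None:
        g, k = len(self.groups), len(self.nutrients)
        self.density = np.asarray(self.density, dtype=float)
        for name in ("ghge", "ced", "lo", "price"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (g, 2):
                raise ValueError(f"{name} must have shape {(g, 2)}, got {arr.shape}")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative entries")
            setattr(self, name, arr)
        if self.density.shape != (g, 2, k):
            raise ValueError(
                f"density must have shape {(g, 2, k)}, got {self.density.shape}"
            )
        if np.any(self.density < 0):
            raise ValueError("nutrient densities must be non-negative")
        self.plant_protein_frac = np.asarray(self.plant_protein_frac, dtype=float)
        if self.plant_protein_frac.shape != (g,):
            raise ValueError("plant_protein_frac must have shape (G,)")
        for i, grp in enumerate(self.groups):
            if grp.id != i:
                raise ValueError("groups must be ordered by id = positional index")
        for required in ("energy_kcal", "protein_g"):
            if required not in self.nutrients:
                raise ValueError(f"nutrient column {required!r} is required")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def nutrient_index(self, name: str) -> int:
        try:
            return self.nutrients.index(name)
        except ValueError:
            raise KeyError(f"unknown nutrient {name!r}") from None

    def nutrient_per_gram(self, name: str) -> np.ndarray:
        """Per-gram density of one nutrient, shape ``(G, 2)``."""
        return self.density[:, :, self.nutrient_index(name)] / 100.0

    def tag_mask(self, tag: str) -> np.ndarray:
        """Boolean mask over groups for one guideline tag.

        Also accepts the prefixed selectors ``category:<c>`` (all groups of
        one category) and ``name:<group_name>`` (a single named group).
        """
        if tag.startswith("category:"):
            cat = tag.split(":", 1)[1]
            if cat not in CATEGORIES:
                raise KeyError(f"unknown category {cat!r}")
            return np.array([grp.category == cat for grp in self.groups])
        if tag.startswith("name:"):
            idx = self.group_index(tag.split(":", 1)[1])
            mask = np.zeros(len(self.groups), dtype=bool)
            mask[idx] = True
            return mask
        return np.array([grp.has_tag(tag) for grp in self.groups])

    def group_index(self, name: str) -> int:
        for grp in self.groups:
            if grp.name == name:
                return grp.id
        raise KeyError(f"unknown food group {name!r}")


@dataclass
class PopulationStats:
    """Weighted consumption statistics per food group, g/d.

    ``coupling_caps`` optionally stores percentiles of *summed* consumption
    over coupled group sets (e.g. refined + wholegrain cereals), keyed by the
    sorted tuple of group ids; they feed the coupled acceptability cap.
    """

    mean: np.ndarray
    sd: np.ndarray
    p95: np.ndarray
    p99: np.ndarray
    energy_requirement: float
    weights_sum: float = 1.0
    coupling_caps: dict[tuple[int, ...], dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("mean", "sd", "p95", "p99"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.sd < 0):
            raise ValueError("weighted SD must be non-negative")
        if np.any(self.mean < 0):
            raise ValueError("weighted mean consumption must be non-negative")
        if np.any(self.p95 > self.p99 + 1e-9):
            raise ValueError("p95 must not exceed p99")
        if self.energy_requirement <= 0:
            raise ValueError("energy requirement must be positive")

    @property
    def n_groups(self) -> int:
        return self.mean.shape[0]

    def percentile(self, level: str) -> np.ndarray:
        if level not in ("p95", "p99"):
            raise KeyError(f"acceptability level must be 'p95' or 'p99', got {level!r}")
        return getattr(self, level)


@dataclass
class DietVector:
    """Decision variables: grams/day per group, split by production mode."""

    q_conv: np.ndarray
    q_org: np.ndarray

    def __post_init__(self) -> None:
        self.q_conv = np.asarray(self.q_conv, dtype=float)
        self.q_org = np.asarray(self.q_org, dtype=float)
        if self.q_conv.shape != self.q_org.shape:
            raise ValueError("q_conv and q_org must share shape")
        if np.any(self.q_conv < -1e-6) or np.any(self.q_org < -1e-6):
            raise ValueError("diet quantities must be non-negative")
        # clip solver-level negative noise
        self.q_conv = np.maximum(self.q_conv, 0.0)
        self.q_org = np.maximum(self.q_org, 0.0)

    @classmethod
    def from_totals(cls, totals: np.ndarray, organic_fraction: float | np.ndarray = 0.0) -> "DietVector":
        totals = np.asarray(totals, dtype=float)
        frac = np.broadcast_to(np.asarray(organic_fraction, dtype=float), totals.shape)
        return cls(q_conv=totals * (1 - frac), q_org=totals * frac)

    @classmethod
    def from_stacked(cls, x: np.ndarray) -> "DietVector":
        x = np.asarray(x, dtype=float)
        g = x.shape[0] // 2
        return cls(q_conv=x[:g], q_org=x[g:])

    @property
    def total(self) -> np.ndarray:
        """Total g/d per group, mode-summed (the Opt_i of the departure sum)."""
        return self.q_conv + self.q_org

    @property
    def n_groups(self) -> int:
        return self.q_conv.shape[0]

    def stacked(self) -> np.ndarray:
        """Flat decision vector ``[q_conv; q_org]`` of length 2G."""
        return np.concatenate([self.q_conv, self.q_org])

    def __add__(self, other: "DietVector") -> "DietVector":
        return DietVector(self.q_conv + other.q_conv, self.q_org + other.q_org)


@dataclass
class DietTotals:
    """Linear aggregates of a diet: nutrients, energy and footprints."""

    nutrients: dict[str, float]
    energy_kcal: float
    ghge: float  # kgCO2eq/d
    ced: float  # MJ/d
    lo: float  # m2/d
    cost: float  # EUR/d
    protein_g: float
    plant_protein_g: float


@dataclass
class Individual:
    """One (synthetic or observed) survey participant at food-group level."""

    consumptions: np.ndarray  # g/d per group
    organic_frequency: Sequence[str]  # five-point scale per group
    weight: float  # sampling weight
    energy_requirement: float  # kcal/d
    energy_intake: float  # kcal/d, from the reported diet

    def __post_init__(self) -> None:
        self.consumptions = np.asarray(self.consumptions, dtype=float)
        if self.weight <= 0:
            raise ValueError("sampling weight must be positive")
        if np.any(self.consumptions < 0):
            raise ValueError("consumptions must be non-negative")

    @property
    def organic_fractions(self) -> np.ndarray:
        return np.array([weight_organic_frequency(m) for m in self.organic_frequency])


def weight_organic_frequency(modality: str) -> float:
    """Map a five-point organic-frequency answer to a mass fraction.

    The survey scale "never", "rarely", "half-of-time", "often", "always"
    is weighted 0, 25, 50, 75 and 100% respectively.
    """
    try:
        return ORGANIC_FREQUENCY_WEIGHTS[modality]
    except KeyError:
        raise ValueError(
            f"unknown organic-frequency modality {modality!r}; "
            f"expected one of {sorted(ORGANIC_FREQUENCY_WEIGHTS)}"
        ) from None


def filter_misreporters(
    population: Sequence[Individual],
    low: float = MISREPORTER_LOW,
    high: float = MISREPORTER_HIGH,
) -> list[Individual]:
    """Drop energy under-/over-reporters.

    Retains individuals whose energy-intake/energy-requirement ratio lies in
    ``[low, high]`` (inclusive: the exclusion rule targets ratios *below* or
    *above* the cut-offs, so equality retains).
    """
    out = []
    for ind in population:
        if ind.energy_requirement <= 0:
            raise ValueError("energy requirement must be positive")
        ratio = ind.energy_intake / ind.energy_requirement
        if low <= ratio <= high:
            out.append(ind)
    return out


def weighted_percentile(values: np.ndarray, weights: np.ndarray, p: float) -> float:
    """Left-continuous inverse of the weighted empirical CDF.

    Returns the lowest observed value whose cumulative weight fraction is
    at least ``p`` (0 < p <= 1).  With unit weights this is the ordinary
    order statistic at ``ceil(p * n)``.
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w) / np.sum(w)
    idx = int(np.searchsorted(cum, p - 1e-12, side="left"))
    idx = min(idx, len(v) - 1)
    return float(v[idx])


def aggregate_population_stats(
    population: Sequence[Individual],
    coupling: Iterable[Sequence[int]] = (),
) -> PopulationStats:
    """Weighted mean, SD and P95/P99 consumption per group.

    The SD is the population-weighted standard deviation (second moment
    about the weighted mean, normalized by the total weight).  Percentiles
    use :func:`weighted_percentile`.  ``coupling`` lists sets of group ids
    whose *summed* consumption percentiles are additionally computed, for
    coupled acceptability caps.
    """
    population = list(population)
    if not population:
        raise ValueError("population is empty")
    w = np.array([ind.weight for ind in population])
    if np.all(w == 0):
        raise ValueError("all sampling weights are zero")
    x = np.stack([ind.consumptions for ind in population])  # (N, G)
    wsum = float(w.sum())
    mean = (w[:, None] * x).sum(axis=0) / wsum
    var = (w[:, None] * (x - mean) ** 2).sum(axis=0) / wsum
    sd = np.sqrt(var)
    g = x.shape[1]
    p95 = np.array([weighted_percentile(x[:, i], w, 0.95) for i in range(g)])
    p99 = np.array([weighted_percentile(x[:, i], w, 0.99) for i in range(g)])
    eer = float((w * np.array([ind.energy_requirement for ind in population])).sum() / wsum)
    coupling_caps: dict[tuple[int, ...], dict[str, float]] = {}
    for group_set in coupling:
        key = tuple(sorted(int(i) for i in group_set))
        s = x[:, list(key)].sum(axis=1)
        coupling_caps[key] = {
            "p95": weighted_percentile(s, w, 0.95),
            "p99": weighted_percentile(s, w, 0.99),
        }
    return PopulationStats(
        mean=mean, sd=sd, p95=np.minimum(p95, p99), p99=p99,
        energy_requirement=eer, weights_sum=wsum, coupling_caps=coupling_caps,
    )


def diet_totals(diet: DietVector, db: FoodDatabase) -> DietTotals:
    """Aggregate a diet into nutrient intakes, energy, footprints and cost.

    Every total is strictly linear in the diet vector:
    ``total = sum_i sum_mode q[i, mode] * density[i, mode]`` with densities
    converted from their storage units (per 100 g for nutrients, per kg for
    footprints and price) to per gram.
    """
    if diet.n_groups != db.n_groups:
        raise ValueError(
            f"diet has {diet.n_groups} groups but database has {db.n_groups}"
        )
    q = np.stack([diet.q_conv, diet.q_org], axis=1)  # (G, 2) g/d
    nutr = {
        name: float((q * db.density[:, :, k] / 100.0).sum())
        for k, name in enumerate(db.nutrients)
    }
    kg = q / 1000.0
    protein = nutr["protein_g"]
    protein_per_group = (q * db.nutrient_per_gram("protein_g")).sum(axis=1)
    plant_protein = float((protein_per_group * db.plant_protein_frac).sum())
    return DietTotals(
        nutrients=nutr,
        energy_kcal=nutr["energy_kcal"],
        ghge=float((kg * db.ghge).sum()),
        ced=float((kg * db.ced).sum()),
        lo=float((kg * db.lo).sum()),
        cost=float((kg * db.price).sum()),
        protein_g=protein,
        plant_protein_g=plant_protein,
    )
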