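"""Shared fixtures and toy-instance factories."""

from __future__ import annotations

import numpy as np
import pytest

from dietopt.food_model import FoodDatabase, FoodGroup, PopulationStats
from dietopt.synthetic_data import default_scenario


def toy_db(
    ghge_conv,
    ghge_org=None,
    energy=None,
    tags=None,
    names=None,
    categories=None,
    extra_nutrients=None,
    plant_protein_frac=None,
) -> FoodDatabase:
    """Build a minimal database for unit tests.

    ``ghge_conv`` / ``ghge_org`` are kgCO2eq/kg per group; ``energy`` is
    kcal per 100 g (defaults to 100 for every group); ``tags`` maps group
    index -> iterable of tag names; ``extra_nutrients`` maps nutrient name
    -> per-100 g densities.
    """
    ghge_conv = np.asarray(ghge_conv, dtype=float)
    g = len(ghge_conv)
    ghge_org = np.asarray(ghge_org, dtype=float) if ghge_org is not None else ghge_conv
    energy = np.asarray(energy, dtype=float) if energy is not None else np.full(g, 100.0)
    tags = tags or {}
    names = names or [f"group{i}" for i in range(g)]
    categories = categories or ["other"] * g
    nutrients = {"energy_kcal": energy, "protein_g": np.full(g, 10.0)}
    if extra_nutrients:
        nutrients.update({k: np.asarray(v, dtype=float) for k, v in extra_nutrients.items()})
    names_list = list(nutrients)
    density = np.stack([np.stack([nutrients[n] for n in names_list], axis=-1)] * 2, axis=1)
    groups = [
        FoodGroup(id=i, name=names[i], category=categories[i],
                  **{t: True for t in tags.get(i, ())})
        for i in range(g)
    ]
    return FoodDatabase(
        groups=groups,
        nutrients=names_list,
        density=density,
        ghge=np.stack([ghge_conv, ghge_org], axis=1),
        ced=np.stack([ghge_conv * 3, ghge_org * 3], axis=1),
        lo=np.stack([ghge_conv, ghge_org], axis=1) * 0.5,
        price=np.full((g, 2), 2.0),
        plant_protein_frac=(np.asarray(plant_protein_frac, dtype=float)
                            if plant_protein_frac is not None else np.zeros(g)),
    )


def toy_stats(mean, sd, p99=None, eer=2500.0) -> PopulationStats:
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    p99 = np.asarray(p99, dtype=float) if p99 is not None else mean * 3 + 100
    return PopulationStats(mean=mean, sd=sd, p95=p99 * 0.9, p99=p99,
                           energy_requirement=eer)


@pytest.fixture(scope="session")
def scenario():
    """The default synthetic main scenario, shared across the suite."""
    return default_scenario(seed=17, n_individuals=2000)
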