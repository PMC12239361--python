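"""Readers and writers for the pipeline's tabular interchange formats.

All tables are UTF-8 CSV with '.' decimal separator; scalar sidecars are
JSON.  Readers validate headers strictly so that a malformed fixture fails
loudly instead of silently misaligning columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .food_model import (
    MODES,
    TAG_NAMES,
    FoodDatabase,
    FoodGroup,
    Individual,
    PopulationStats,
)
from .indicators import RiskFactor, TmrelTable

__all__ = [
    "write_food_db",
    "read_food_db",
    "write_population_stats",
    "read_population_stats",
    "write_population",
    "read_population",
    "write_tmrel",
    "read_tmrel",
]


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required columns {missing}")


def write_food_db(db: FoodDatabase, path: str | Path) -> None:
    """Write the per-group, per-mode database (one row per group x mode)."""
    rows = []
    for grp in db.groups:
        for m, mode in enumerate(MODES):
            row: dict = {
                "group_id": grp.id,
                "group_name": grp.name,
                "category": grp.category,
                "mode": mode,
            }
            for tag in TAG_NAMES:
                row[tag] = int(grp.has_tag(tag))
            for k, nutrient in enumerate(db.nutrients):
                row[nutrient] = db.density[grp.id, m, k]
            row["ghge_kg"] = db.ghge[grp.id, m]
            row["ced_mj"] = db.ced[grp.id, m]
            row["lo_m2"] = db.lo[grp.id, m]
            row["price_eur"] = db.price[grp.id, m]
            row["plant_protein_frac"] = db.plant_protein_frac[grp.id]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_food_db(path: str | Path) -> FoodDatabase:
    df = pd.read_csv(path)
    meta = ["group_id", "group_name", "category", "mode"]
    footprints = ["ghge_kg", "ced_mj", "lo_m2", "price_eur", "plant_protein_frac"]
    _check_columns(df, meta + list(TAG_NAMES) + footprints, "food database")
    nutrients = [c for c in df.columns
                 if c not in meta + list(TAG_NAMES) + footprints]
    if not nutrients:
        raise ValueError("food database: no nutrient columns found")
    ids = sorted(df["group_id"].unique())
    if ids != list(range(len(ids))):
        raise ValueError("food database: group_id must be contiguous from 0")
    g, k = len(ids), len(nutrients)
    density = np.zeros((g, 2, k))
    ghge = np.zeros((g, 2))
    ced = np.zeros((g, 2))
    lo = np.zeros((g, 2))
    price = np.zeros((g, 2))
    ppf = np.zeros(g)
    groups: list[FoodGroup | None] = [None] * g
    for _, row in df.iterrows():
        i = int(row["group_id"])
        if row["mode"] not in MODES:
            raise ValueError(f"food database: unknown mode {row['mode']!r}")
        m = MODES.index(row["mode"])
        if groups[i] is None:
            groups[i] = FoodGroup(
                id=i, name=str(row["group_name"]), category=str(row["category"]),
                **{tag: bool(row[tag]) for tag in TAG_NAMES},
            )
        density[i, m] = [row[n] for n in nutrients]
        ghge[i, m] = row["ghge_kg"]
        ced[i, m] = row["ced_mj"]
        lo[i, m] = row["lo_m2"]
        price[i, m] = row["price_eur"]
        ppf[i] = row["plant_protein_frac"]
    counts = df.groupby("group_id")["mode"].nunique()
    if (counts != 2).any():
        raise ValueError("food database: every group needs both production modes")
    return FoodDatabase(groups=[grp for grp in groups if grp is not None],
                        nutrients=nutrients, density=density, ghge=ghge,
                        ced=ced, lo=lo, price=price, plant_protein_frac=ppf)


def write_population_stats(stats: PopulationStats, csv_path: str | Path,
                           json_path: str | Path) -> None:
    """Write per-group stats as CSV plus a JSON sidecar for the scalars."""
    pd.DataFrame({
        "group_id": np.arange(stats.n_groups),
        "mean": stats.mean,
        "sd": stats.sd,
        "p95": stats.p95,
        "p99": stats.p99,
    }).to_csv(csv_path, index=False)
    sidecar = {
        "energy_requirement": stats.energy_requirement,
        "weights_sum": stats.weights_sum,
        "coupling_caps": {
            ",".join(map(str, key)): val for key, val in stats.coupling_caps.items()
        },
    }
    Path(json_path).write_text(json.dumps(sidecar, indent=2))


def read_population_stats(csv_path: str | Path, json_path: str | Path) -> PopulationStats:
    df = pd.read_csv(csv_path)
    _check_columns(df, ["group_id", "mean", "sd", "p95", "p99"], "population stats")
    df = df.sort_values("group_id")
    sidecar = json.loads(Path(json_path).read_text())
    caps = {
        tuple(int(i) for i in key.split(",")): {k: float(v) for k, v in val.items()}
        for key, val in sidecar.get("coupling_caps", {}).items()
    }
    return PopulationStats(
        mean=df["mean"].to_numpy(), sd=df["sd"].to_numpy(),
        p95=df["p95"].to_numpy(), p99=df["p99"].to_numpy(),
        energy_requirement=float(sidecar["energy_requirement"]),
        weights_sum=float(sidecar.get("weights_sum", 1.0)),
        coupling_caps=caps,
    )


def write_population(population: Sequence[Individual], db: FoodDatabase,
                     path: str | Path) -> None:
    """Write individual rows (consumptions and organic answers per group)."""
    names = [grp.name for grp in db.groups]
    rows = []
    for i, ind in enumerate(population):
        row: dict = {
            "individual_id": i,
            "weight": ind.weight,
            "energy_requirement": ind.energy_requirement,
            "energy_intake": ind.energy_intake,
        }
        for name, q, mod in zip(names, ind.consumptions, ind.organic_frequency):
            row[f"g_{name}"] = q
            row[f"org_{name}"] = mod
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_population(path: str | Path, db: FoodDatabase) -> list[Individual]:
    df = pd.read_csv(path)
    names = [grp.name for grp in db.groups]
    required = (["individual_id", "weight", "energy_requirement", "energy_intake"]
                + [f"g_{n}" for n in names] + [f"org_{n}" for n in names])
    _check_columns(df, required, "population")
    out = []
    for _, row in df.iterrows():
        out.append(Individual(
            consumptions=np.array([row[f"g_{n}"] for n in names], dtype=float),
            organic_frequency=[str(row[f"org_{n}"]) for n in names],
            weight=float(row["weight"]),
            energy_requirement=float(row["energy_requirement"]),
            energy_intake=float(row["energy_intake"]),
        ))
    return out


def write_tmrel(tmrel: TmrelTable, path: str | Path) -> None:
    pd.DataFrame([{
        "risk_factor": rf.name,
        "tmrel": rf.tmrel,
        "max_deviation": rf.max_deviation,
        "direction": rf.direction,
        "selector": rf.selector,
        "weight": rf.weight,
    } for rf in tmrel]).to_csv(path, index=False)


def read_tmrel(path: str | Path) -> TmrelTable:
    df = pd.read_csv(path)
    _check_columns(df, ["risk_factor", "tmrel", "max_deviation", "direction",
                        "selector", "weight"], "TMREL table")
    return TmrelTable([
        RiskFactor(
            name=str(row["risk_factor"]), tmrel=float(row["tmrel"]),
            max_deviation=float(row["max_deviation"]),
            direction=str(row["direction"]), selector=str(row["selector"]),
            weight=float(row["weight"]),
        )
        for _, row in df.iterrows()
    ])
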