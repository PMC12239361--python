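"""Tabular report assembly for solved models.

Builds the per-model indicator tables, the per-level grid panels and the
group-contribution matrices behind the usual presentation of this kind of
analysis (one indicator column per model; per-level food-group GHGe
contributions).  Food groups can be pooled into broader display
categories for readability; the display regrouping never feeds back into
optimization.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .food_model import MODES, DietVector, FoodDatabase, PopulationStats
from .indicators import TmrelTable, panel
from .optimizer import GridScanResult, Solution
from .synthetic_data import DISPLAY_REGROUPING

__all__ = [
    "diet_frame",
    "panel_row",
    "solutions_table",
    "scan_table",
    "contributions_table",
    "sensitivity_table",
    "config_hash",
    "write_solution_bundle",
]


def diet_frame(diet: DietVector, db: FoodDatabase) -> pd.DataFrame:
    """One row per group x mode with consumed grams/day."""
    rows = []
    for grp in db.groups:
        for mode, q in zip(MODES, (diet.q_conv[grp.id], diet.q_org[grp.id])):
            rows.append({"group_id": grp.id, "group_name": grp.name,
                         "mode": mode, "g_per_d": float(q)})
    return pd.DataFrame(rows)


def panel_row(name: str, solution: Solution, db: FoodDatabase,
              stats: PopulationStats, tmrel: TmrelTable) -> dict:
    """Indicator-panel dict for one solved model (NaNs when infeasible)."""
    row: dict = {"model": name, "status": solution.status}
    if solution.ok and solution.diet is not None:
        p = panel(solution.diet, db, stats, tmrel)
        row.update(p.as_dict())
    return row


def solutions_table(named_solutions: Mapping[str, Solution], db: FoodDatabase,
                    stats: PopulationStats, tmrel: TmrelTable) -> pd.DataFrame:
    return pd.DataFrame([
        panel_row(name, sol, db, stats, tmrel)
        for name, sol in named_solutions.items()
    ])


def scan_table(scan: GridScanResult, db: FoodDatabase, stats: PopulationStats,
               tmrel: TmrelTable) -> pd.DataFrame:
    """One row per grid level (M0, M1, ...) with the full indicator panel."""
    rows = []
    for k, (g, sol) in enumerate(zip(scan.targets, scan.solutions)):
        row = panel_row(scan.level_name(k), sol, db, stats, tmrel)
        row["ghge_target"] = float(g)
        rows.append(row)
    return pd.DataFrame(rows)


def _display_category(name: str) -> str:
    return DISPLAY_REGROUPING.get(name, name)


def contributions_table(scan: GridScanResult, db: FoodDatabase,
                        pooled: bool = True) -> pd.DataFrame:
    """Per-level GHGe contribution of each (display) food group, kgCO2eq/d.

    Contributions partition the level total exactly: summing a row's
    group columns reproduces the diet's GHGe.
    """
    rows = []
    for k, sol in enumerate(scan.solutions):
        if not sol.ok or sol.diet is None:
            continue
        q = np.stack([sol.diet.q_conv, sol.diet.q_org], axis=1) / 1000.0
        per_group = (q * db.ghge).sum(axis=1)
        row: dict = {"model": scan.level_name(k),
                     "ghge_target": float(scan.targets[k])}
        for grp in db.groups:
            key = _display_category(grp.name) if pooled else grp.name
            row[key] = row.get(key, 0.0) + float(per_group[grp.id])
        rows.append(row)
    return pd.DataFrame(rows).fillna(0.0)


def sensitivity_table(cap_solutions: Mapping[float, Solution], db: FoodDatabase,
                      stats: PopulationStats, tmrel: TmrelTable) -> pd.DataFrame:
    """Indicator panel per total-meat cap (g/wk), highest cap first."""
    rows = []
    for cap in sorted(cap_solutions, reverse=True):
        row = panel_row(f"M{cap:g}", cap_solutions[cap], db, stats, tmrel)
        row["meat_cap_g_wk"] = float(cap)
        rows.append(row)
    return pd.DataFrame(rows)


def config_hash(config: Mapping) -> str:
    """Short provenance hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_solution_bundle(outdir: str | Path, name: str, solution: Solution,
                          db: FoodDatabase, stats: PopulationStats,
                          tmrel: TmrelTable, meta: Mapping | None = None) -> None:
    """Write one model's diet CSV and indicator JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record: dict = {
        "model": name,
        "status": solution.status,
        "objective_value": solution.objective_value,
        "td": solution.td,
        "active_constraints": solution.active_constraints,
        "infeasible_provenances": solution.infeasible_provenances,
        "message": solution.message,
    }
    if meta:
        record.update(meta)
    if solution.ok and solution.diet is not None:
        diet_frame(solution.diet, db).to_csv(outdir / f"{name}_diet.csv", index=False)
        record["indicators"] = panel(solution.diet, db, stats, tmrel).as_dict()
    (outdir / f"{name}.json").write_text(json.dumps(record, indent=2))
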