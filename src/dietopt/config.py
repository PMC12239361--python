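"""Run configuration: one YAML document drives a whole analysis run.

Defaults mirror the main scenario: P99 acceptability, 500 g/wk red-meat
cap, 0.2 kgCO2eq/d grid step, nuts floor 15 g/d, dairy at exactly two
portions per day.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .constraints import (
    AcceptabilityConfig,
    BioavailabilityParams,
    FbdgConfig,
    NutrientReference,
)

__all__ = ["RunConfig", "load_config", "NutrientBoundModel"]


class NutrientBoundModel(BaseModel):
    nutrient: str
    lower: Optional[float] = None
    upper: Optional[float] = None
    unit: str = "per day"

    def to_reference(self) -> NutrientReference:
        return NutrientReference(self.nutrient, self.lower, self.upper, self.unit)


class FbdgModel(BaseModel):
    fruit_veg_min_g: float = 400.0
    juice_portion_g: float = 150.0
    juice_max_g: float = 150.0
    nuts_min_g: float = 15.0
    pulses_min_g_wk: float = 400.0
    dairy_portions: float = 2.0
    dairy_portion_band: float = 0.0
    wholegrain_min_g_wk: float = 400.0
    red_meat_max_g_wk: float = 500.0
    processed_meat_max_g_wk: float = 150.0
    seafood_min_g_wk: float = 200.0
    fatty_fish_min_g_wk: float = 100.0
    added_fat_energy_frac_max: float = 0.16
    sweet_drinks_zero: bool = True
    alcohol_max_g: Optional[float] = None

    def to_config(self) -> FbdgConfig:
        return FbdgConfig(**self.model_dump())


class AcceptabilityModel(BaseModel):
    level: str = "p99"
    coupling_tags: list[list[str]] = Field(
        default_factory=lambda: [["is_refined_cereal", "is_wholegrain"]]
    )
    exempt_tags: list[str] = Field(default_factory=lambda: ["is_pulse"])

    @field_validator("level")
    @classmethod
    def _level_ok(cls, v: str) -> str:
        if v not in ("p95", "p99"):
            raise ValueError("acceptability level must be 'p95' or 'p99'")
        return v

    def to_config(self) -> AcceptabilityConfig:
        return AcceptabilityConfig(
            level=self.level,
            coupling_tags=tuple(tuple(s) for s in self.coupling_tags),
            exempt_tags=tuple(self.exempt_tags),
        )


class BioavailabilityModelCfg(BaseModel):
    model: str = "parametric"
    iron_base: float = 0.10
    zinc_base: float = 0.25
    lower_bounds: dict[str, float] = Field(
        default_factory=lambda: {"iron": 0.8, "zinc": 1.8}
    )

    def to_params(self) -> BioavailabilityParams:
        return BioavailabilityParams(iron_base=self.iron_base, zinc_base=self.zinc_base)


class GridModel(BaseModel):
    gmin: Optional[float] = None  # None: derived from the extremum models
    gmax: Optional[float] = None
    step: float = 0.2


class RunConfig(BaseModel):
    """Validated configuration for CLI runs."""

    db_path: Optional[str] = None
    stats_csv: Optional[str] = None
    stats_json: Optional[str] = None
    tmrel_path: Optional[str] = None
    outdir: str = "results"
    seed: int = 17
    n_individuals: int = 2000
    objectives: list[str] = Field(default_factory=lambda: ["min_TD", "min_GHGe", "max_GHGe"])
    grid: GridModel = Field(default_factory=GridModel)
    meat_caps_g_wk: list[float] = Field(default_factory=lambda: [500, 400, 300, 200])
    nutrients: list[NutrientBoundModel] = Field(default_factory=list)
    fbdg: FbdgModel = Field(default_factory=FbdgModel)
    acceptability: AcceptabilityModel = Field(default_factory=AcceptabilityModel)
    bioavailability: BioavailabilityModelCfg = Field(default_factory=BioavailabilityModelCfg)

    def require_paths(self) -> None:
        for attr in ("db_path", "stats_csv", "stats_json", "tmrel_path"):
            value = getattr(self, attr)
            if value is None:
                raise ValueError(f"config field {attr} is required for this command")
            if not Path(value).exists():
                raise FileNotFoundError(f"{attr}: no such file {value!r}")


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
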