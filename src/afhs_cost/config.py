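"""Model configuration: a directory of CSV tables plus a settings file.

A configuration directory contains

* ``settings.yaml`` — schema version, number of countries, anchor year,
  annualization divisor, generator seed (if synthetic);
* ``countries.csv``, ``interventions.csv``, ``characteristics.csv`` — the
  registry tables;
* ``need_params.csv`` — country x intervention need shares (validated
  against the catalogue ranges);
* ``baselines.csv`` — country x intervention 2010 coverage baselines
  (validated against the catalogue ranges);
* ``ingredients.csv`` — per-intervention ingredient lines;
* ``unit_costs.csv`` — country x delivery-level service unit costs;
* ``programme_activities.csv`` — activity components (one row per item);
* ``drivers.csv`` — district and facility counts per country.

Loading is all-or-nothing: any validation error aborts with no partial
configuration.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .costing import IngredientLine, ProgrammeActivitySpec
from .errors import SchemaError, ValidationError
from .registry import (
    SCHEMA_VERSION,
    AfhsCharacteristic,
    Country,
    InterventionSpec,
    load_characteristics,
    load_country_table,
    load_intervention_table,
)

CONFIG_FILES = (
    "settings.yaml",
    "countries.csv",
    "interventions.csv",
    "characteristics.csv",
    "need_params.csv",
    "baselines.csv",
    "ingredients.csv",
    "unit_costs.csv",
    "programme_activities.csv",
    "drivers.csv",
)


@dataclass(frozen=True)
class Settings:
    schema_version: str = SCHEMA_VERSION
    n_countries: int = 74
    anchor_year: int = 2010
    annualization_years: int = 5
    seed: int | None = None


@dataclass(frozen=True)
class ModelConfig:
    settings: Settings
    countries: tuple[Country, ...]
    interventions: tuple[InterventionSpec, ...]
    characteristics: tuple[AfhsCharacteristic, ...]
    need_params: pd.DataFrame      # country_id, intervention_id, need_share
    baselines: pd.DataFrame        # country_id, intervention_id, baseline
    ingredients: tuple[IngredientLine, ...]
    unit_costs: pd.DataFrame       # country_id, level, unit_cost
    activities: tuple[ProgrammeActivitySpec, ...]
    drivers: pd.DataFrame          # country_id, n_districts, n_facilities
    config_hash: str = ""

    def country(self, country_id: str) -> Country:
        for c in self.countries:
            if c.country_id == country_id:
                return c
        raise ValidationError(f"unknown country {country_id!r}")

    def intervention(self, intervention_id: str) -> InterventionSpec:
        for s in self.interventions:
            if s.intervention_id == intervention_id:
                return s
        raise ValidationError(f"unknown intervention {intervention_id!r}")

    def need_share(self, country_id: str, intervention_id: str) -> float:
        return float(self._lookup(self.need_params, country_id, intervention_id, "need_share"))

    def baseline(self, country_id: str, intervention_id: str) -> float:
        return float(self._lookup(self.baselines, country_id, intervention_id, "baseline"))

    def unit_cost_map(self, country_id: str) -> dict[str, float]:
        rows = self.unit_costs[self.unit_costs["country_id"] == country_id]
        if rows.empty:
            raise ValidationError(f"no service unit costs for {country_id!r}")
        return dict(zip(rows["level"], rows["unit_cost"].astype(float)))

    def driver_map(self, country_id: str) -> dict[str, float]:
        rows = self.drivers[self.drivers["country_id"] == country_id]
        if rows.empty:
            raise ValidationError(f"no driver counts for {country_id!r}")
        row = rows.iloc[0]
        return {"n_districts": float(row["n_districts"]),
                "n_facilities": float(row["n_facilities"])}

    @staticmethod
    def _lookup(df: pd.DataFrame, cid: str, iid: str, col: str):
        rows = df[(df["country_id"] == cid) & (df["intervention_id"] == iid)]
        if rows.empty:
            raise ValidationError(f"no {col} configured for {cid}/{iid}")
        return rows.iloc[0][col]


def _read_table(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"configuration file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} is missing required columns {missing}")
    for col in ("country_id", "intervention_id", "activity_id", "level"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return df


def load_ingredient_table(path: Path) -> tuple[IngredientLine, ...]:
    df = _read_table(path, ["intervention_id", "item", "category",
                            "quantity_per_case", "unit_price", "delivery_point"])
    lines = []
    for _, r in df.iterrows():
        price = None if pd.isna(r["unit_price"]) else float(r["unit_price"])
        lines.append(IngredientLine(
            intervention_id=str(r["intervention_id"]),
            item=r["item"],
            category=r["category"],
            quantity_per_case=float(r["quantity_per_case"]),
            unit_price=price,
            delivery_point=r["delivery_point"],
        ))
    return tuple(lines)


def load_activity_table(path: Path) -> tuple[ProgrammeActivitySpec, ...]:
    df = _read_table(path, ["activity_id", "category", "level", "scaling_driver",
                            "item", "quantity", "unit_price"])
    specs = []
    for aid, grp in df.groupby("activity_id", sort=True):
        heads = grp[["category", "level", "scaling_driver"]].drop_duplicates()
        if len(heads) != 1:
            raise ValidationError(f"activity {aid!r} has inconsistent header fields")
        specs.append(ProgrammeActivitySpec(
            activity_id=str(aid),
            category=grp.iloc[0]["category"],
            level=grp.iloc[0]["level"],
            scaling_driver=grp.iloc[0]["scaling_driver"],
            components=tuple(
                (r["item"], float(r["quantity"]), float(r["unit_price"]))
                for _, r in grp.iterrows()
            ),
        ))
    return tuple(specs)


def config_dir_hash(config_dir: Path) -> str:
    """SHA-256 over the byte content of all configuration files, in a fixed order."""
    h = hashlib.sha256()
    for name in CONFIG_FILES:
        p = config_dir / name
        if p.exists():
            h.update(name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def load_config(config_dir: str | Path) -> ModelConfig:
    """Load and cross-validate a full configuration directory."""
    config_dir = Path(config_dir)
    settings_path = config_dir / "settings.yaml"
    if not settings_path.exists():
        raise SchemaError(f"missing {settings_path}")
    raw = yaml.safe_load(settings_path.read_text()) or {}
    settings = Settings(
        schema_version=str(raw.get("schema_version", SCHEMA_VERSION)),
        n_countries=int(raw.get("n_countries", 74)),
        anchor_year=int(raw.get("anchor_year", 2010)),
        annualization_years=int(raw.get("annualization_years", 5)),
        seed=raw.get("seed"),
    )
    countries = load_country_table(
        config_dir / "countries.csv",
        schema_version=settings.schema_version,
        expected_count=settings.n_countries,
    )
    interventions = load_intervention_table(config_dir / "interventions.csv")
    characteristics = load_characteristics(config_dir / "characteristics.csv")
    need_params = _read_table(config_dir / "need_params.csv",
                              ["country_id", "intervention_id", "need_share"])
    baselines = _read_table(config_dir / "baselines.csv",
                            ["country_id", "intervention_id", "baseline"])
    ingredients = load_ingredient_table(config_dir / "ingredients.csv")
    unit_costs = _read_table(config_dir / "unit_costs.csv",
                             ["country_id", "level", "unit_cost"])
    activities = load_activity_table(config_dir / "programme_activities.csv")
    drivers = _read_table(config_dir / "drivers.csv",
                          ["country_id", "n_districts", "n_facilities"])

    spec_by_id = {s.intervention_id: s for s in interventions}
    for _, r in need_params.iterrows():
        spec = spec_by_id.get(str(r["intervention_id"]))
        if spec is None:
            raise ValidationError(f"need_params references unknown intervention {r['intervention_id']!r}")
        lo, hi = spec.need_share_range
        if not (lo - 1e-12 <= float(r["need_share"]) <= hi + 1e-12):
            raise ValidationError(
                f"need share {r['need_share']} for {r['country_id']}/{spec.intervention_id} "
                f"outside range [{lo}, {hi}]"
            )
    for _, r in baselines.iterrows():
        spec = spec_by_id.get(str(r["intervention_id"]))
        if spec is None:
            raise ValidationError(f"baselines references unknown intervention {r['intervention_id']!r}")
        lo, hi = spec.coverage_range
        if not (lo - 1e-12 <= float(r["baseline"]) <= hi + 1e-12):
            raise ValidationError(
                f"baseline {r['baseline']} for {r['country_id']}/{spec.intervention_id} "
                f"outside coverage range [{lo}, {hi}]"
            )

    return ModelConfig(
        settings=settings,
        countries=tuple(countries),
        interventions=tuple(interventions),
        characteristics=tuple(characteristics),
        need_params=need_params,
        baselines=baselines,
        ingredients=ingredients,
        unit_costs=unit_costs,
        activities=activities,
        drivers=drivers,
        config_hash=config_dir_hash(config_dir),
    )
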