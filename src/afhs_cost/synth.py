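"""Synthetic configuration generator.

The detailed ingredient quantities and unit prices behind the costing model
live in external price databases and are not packaged; this module generates
complete, internally consistent stand-in configurations so that every stage
of the pipeline is testable offline:

* coverage baselines drawn within each intervention's catalogue range
  (uniform, or the range midpoint);
* need shares drawn within the catalogue need ranges;
* service-delivery unit costs log-normally dispersed around level-specific
  anchors (hospital > primary facility > community contact), per country;
* commodity prices log-normally dispersed around the illustrative packaged
  catalogue (one global price per item);
* district/facility counts derived from population size;
* per-country population growth rates drawn within a configurable range.

All prices are order-of-magnitude plausible but explicitly illustrative.
Everything is reproducible from the seed. Delivery-point shares and
coverage targets are never randomized: they are fixed model structure.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import pydantic
import yaml

from .config import ModelConfig, load_config
from .costing import CUBE_COLUMNS
from .errors import ValidationError
from .registry import InterventionSpec, default_data_path, load_intervention_table

#: Anchor US$ (2008) per service contact by delivery level.
UNIT_COST_ANCHORS = {"hospital": 15.0, "primary": 4.0, "community": 1.5}


class SynthConfig(pydantic.BaseModel):
    """Parameters of the synthetic configuration generator."""

    model_config = pydantic.ConfigDict(frozen=True)

    seed: int
    n_countries: int = pydantic.Field(default=74, ge=1)
    price_dispersion: float = pydantic.Field(default=0.3, ge=0.0, description="CV of prices")
    baseline_mode: Literal["range_uniform", "range_midpoint"] = "range_uniform"
    growth_rate_range: tuple[float, float] = (0.005, 0.03)


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Positive multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv <= 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=n))


def sample_baselines(
    interventions: Sequence[InterventionSpec],
    country_ids: Sequence[str],
    rng: np.random.Generator,
    mode: str = "range_uniform",
) -> pd.DataFrame:
    """Draw a 2010 coverage baseline per country x intervention.

    ``range_uniform`` draws uniformly within the intervention's catalogue
    coverage range; ``range_midpoint`` sets every country to the midpoint.
    """
    rows = []
    for spec in interventions:
        lo, hi = spec.coverage_range
        if mode == "range_midpoint":
            values = np.full(len(country_ids), (lo + hi) / 2.0)
        else:
            values = rng.uniform(lo, hi, size=len(country_ids))
        for cid, v in zip(country_ids, values):
            rows.append({"country_id": cid, "intervention_id": spec.intervention_id,
                         "baseline": float(v)})
    return pd.DataFrame(rows)


def sample_need_shares(
    interventions: Sequence[InterventionSpec],
    country_ids: Sequence[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw a need share per country x intervention within the catalogue range."""
    rows = []
    for spec in interventions:
        lo, hi = spec.need_share_range
        values = rng.uniform(lo, hi, size=len(country_ids))
        for cid, v in zip(country_ids, values):
            rows.append({"country_id": cid, "intervention_id": spec.intervention_id,
                         "need_share": float(v)})
    return pd.DataFrame(rows)


def generate_config(sc: SynthConfig, out_dir: str | Path) -> Path:
    """Emit a full configuration directory; identical for identical seeds."""
    registry = pd.read_csv(default_data_path("countries.csv"))
    if sc.n_countries > len(registry):
        raise ValidationError(
            f"n_countries {sc.n_countries} exceeds the fixed registry of {len(registry)}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(sc.seed)

    countries = registry.iloc[: sc.n_countries].copy()
    lo_g, hi_g = sc.growth_rate_range
    countries["pop_growth_rate"] = np.round(rng.uniform(lo_g, hi_g, size=len(countries)), 6)
    # total population from a drawn adolescent share of 18-25%
    adol_share = rng.uniform(0.18, 0.25, size=len(countries))
    countries["total_pop_2010_thousands"] = np.round(
        countries["adol_pop_2010_thousands"] / adol_share
    ).astype(int)
    countries.to_csv(out_dir / "countries.csv", index=False)

    for name in ("interventions.csv", "characteristics.csv", "programme_activities.csv"):
        (out_dir / name).write_bytes(default_data_path(name).read_bytes())

    interventions = load_intervention_table(out_dir / "interventions.csv")
    cids = list(countries["country_id"])

    sample_need_shares(interventions, cids, rng).to_csv(out_dir / "need_params.csv", index=False)
    sample_baselines(interventions, cids, rng, sc.baseline_mode).to_csv(
        out_dir / "baselines.csv", index=False
    )

    uc_rows = []
    for level, anchor in UNIT_COST_ANCHORS.items():
        factors = _lognormal_factors(rng, sc.price_dispersion, len(cids))
        for cid, f in zip(cids, factors):
            uc_rows.append({"country_id": cid, "level": level,
                            "unit_cost": round(anchor * float(f), 4)})
    pd.DataFrame(uc_rows).sort_values(["country_id", "level"]).to_csv(
        out_dir / "unit_costs.csv", index=False
    )

    ingredients = pd.read_csv(default_data_path("ingredients.csv"))
    commodity = ingredients["category"] != "service_delivery"
    factors = _lognormal_factors(rng, sc.price_dispersion, int(commodity.sum()))
    ingredients.loc[commodity, "unit_price"] = np.round(
        ingredients.loc[commodity, "unit_price"].to_numpy() * factors, 6
    )
    ingredients.to_csv(out_dir / "ingredients.csv", index=False)

    drivers = pd.DataFrame({
        "country_id": countries["country_id"],
        "n_districts": np.maximum(
            1, np.round(countries["total_pop_2010_thousands"] / 500)
        ).astype(int),
        "n_facilities": np.maximum(
            5, np.round(countries["adol_pop_2010_thousands"] / 20)
        ).astype(int),
    })
    drivers.to_csv(out_dir / "drivers.csv", index=False)

    settings = {
        "schema_version": "1",
        "n_countries": int(sc.n_countries),
        "anchor_year": 2010,
        "annualization_years": 5,
        "seed": int(sc.seed),
        "generator": {
            "price_dispersion": sc.price_dispersion,
            "baseline_mode": sc.baseline_mode,
            "growth_rate_range": list(sc.growth_rate_range),
        },
    }
    (out_dir / "settings.yaml").write_text(yaml.safe_dump(settings, sort_keys=True))
    return out_dir


# ---------------------------------------------------------------------------
# Toy worked example: 2 countries x 2 interventions, hand-computable.

_TOY_COUNTRIES = [
    # id, name, adol (thousands), total (thousands), growth, h/p/c unit cost, districts, facilities
    ("TOA", "Toyland A", 100, 500, 0.02, 10.0, 4.0, 2.0, 2, 10),
    ("TOB", "Toyland B", 200, 900, 0.00, 8.0, 3.0, 1.0, 3, 20),
]

# X1: all adolescents, need 10%, baseline 20% -> 95%, hospital/primary 50/50,
#     drug 2 x $1.50 plus 2 contacts. X2: female adolescents, need 30%,
#     baseline 50% -> 95%, primary only, drug 1 x $2.00 plus 1 contact.
_TOY_X1 = {"need": 0.10, "baseline": 0.20, "target": 0.95, "drug_cost": 3.0, "contacts": 2}
_TOY_X2 = {"need": 0.30, "baseline": 0.50, "target": 0.95, "drug_cost": 2.0, "contacts": 1}
_TOY_MGMT = 50_000.0        # per country-year
_TOY_TRAINING = 500.0       # per facility-year
_TOY_IEC = 100.0            # per 1,000 adolescents per year


def expected_toy_cube(baseline_equals_target: bool = False) -> pd.DataFrame:
    """The toy cube computed directly from the documented closed forms.

    Written as plain scalar arithmetic, independently of the engine modules,
    so it can double as the end-to-end regression oracle (and be checked in
    a spreadsheet).
    """
    records = []
    for cid, _, adol_k, _, growth, h, p, _, _, n_fac in _TOY_COUNTRIES:
        for year in range(2011, 2016):
            k = year - 2010
            pop = adol_k * 1000.0 * (1.0 + growth) ** k
            for iid, t, cpc_svc in (
                ("X1", _TOY_X1, _TOY_X1["contacts"] * (0.5 * h + 0.5 * p)),
                ("X2", _TOY_X2, _TOY_X2["contacts"] * p),
            ):
                eligible = pop if iid == "X1" else 0.5 * pop
                baseline = t["target"] if baseline_equals_target else t["baseline"]
                increment = (k / 5.0) * (t["target"] - baseline)
                cases = eligible * t["need"] * increment
                records.append((cid, iid, "intervention", year, "commodities",
                                cases * t["drug_cost"]))
                records.append((cid, iid, "intervention", year, "service_delivery",
                                cases * cpc_svc))
            records.append((cid, "mgmt", "programme_activity", year, "programme", _TOY_MGMT))
            records.append((cid, "training", "programme_activity", year, "programme",
                            _TOY_TRAINING * n_fac))
            records.append((cid, "iec", "programme_activity", year, "programme",
                            _TOY_IEC * pop / 1000.0))
    df = pd.DataFrame(records, columns=CUBE_COLUMNS)
    return df.sort_values(CUBE_COLUMNS[:5], kind="mergesort").reset_index(drop=True)


def make_toy_worked_example(
    out_dir: str | Path, baseline_equals_target: bool = False
) -> tuple[ModelConfig, pd.DataFrame]:
    """Emit the 2-country, 2-intervention toy configuration and its expected cube."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    head = pd.read_csv(default_data_path("countries.csv")).columns
    c_rows = []
    for cid, name, adol_k, total_k, growth, *_ in _TOY_COUNTRIES:
        c_rows.append({
            "country_id": cid, "name": name, "who_region": "AFR_D",
            "income_group": "low" if cid == "TOA" else "middle",
            "adol_pop_2010_thousands": adol_k, "total_pop_2010_thousands": total_k,
            "pop_growth_rate": growth,
            "hiv_prev_boys_pct": 1.0, "hiv_prev_girls_pct": 1.5,
            "sex_active_10_14_boys_pct": 10.0, "sex_active_10_14_girls_pct": 12.0,
            "sex_active_15_19_boys_pct": 40.0, "sex_active_15_19_girls_pct": 50.0,
            "hiv_prev_boys_src": "observed", "hiv_prev_girls_src": "observed",
            "sex_active_10_14_boys_src": "observed", "sex_active_10_14_girls_src": "observed",
            "sex_active_15_19_boys_src": "observed", "sex_active_15_19_girls_src": "observed",
            "excluded_from_maternity": False, "excluded_from_programme": False,
            "abortion_legal": True, "harm_reduction_permitted": True,
        })
    pd.DataFrame(c_rows, columns=head).to_csv(out_dir / "countries.csv", index=False)

    pd.DataFrame([
        {"intervention_id": "X1", "name": "Toy service X1", "group": "toy_group_1",
         "package": "preventive_essential", "need_basis": "all_adolescents",
         "need_lo": _TOY_X1["need"], "need_hi": _TOY_X1["need"],
         "coverage_lo": 0.0, "coverage_hi": 0.95, "target_coverage": _TOY_X1["target"],
         "share_hospital": 0.5, "share_primary": 0.5, "share_community": 0.0,
         "sex_filter": "both", "requires_abortion_legal": False,
         "requires_harm_reduction": False, "costed_in": "main_model"},
        {"intervention_id": "X2", "name": "Toy service X2", "group": "toy_group_2",
         "package": "curative_essential", "need_basis": "female_adolescents",
         "need_lo": _TOY_X2["need"], "need_hi": _TOY_X2["need"],
         "coverage_lo": 0.0, "coverage_hi": 0.95, "target_coverage": _TOY_X2["target"],
         "share_hospital": 0.0, "share_primary": 1.0, "share_community": 0.0,
         "sex_filter": "female", "requires_abortion_legal": False,
         "requires_harm_reduction": False, "costed_in": "main_model"},
    ]).to_csv(out_dir / "interventions.csv", index=False)

    (out_dir / "characteristics.csv").write_bytes(
        default_data_path("characteristics.csv").read_bytes()
    )

    rows = []
    for cid, *_ in _TOY_COUNTRIES:
        for iid, t in (("X1", _TOY_X1), ("X2", _TOY_X2)):
            baseline = t["target"] if baseline_equals_target else t["baseline"]
            rows.append({"country_id": cid, "intervention_id": iid,
                         "need_share": t["need"], "baseline": baseline})
    df = pd.DataFrame(rows)
    df[["country_id", "intervention_id", "need_share"]].to_csv(
        out_dir / "need_params.csv", index=False
    )
    df[["country_id", "intervention_id", "baseline"]].to_csv(
        out_dir / "baselines.csv", index=False
    )

    pd.DataFrame([
        {"intervention_id": "X1", "item": "toy drug A", "category": "drug",
         "quantity_per_case": 2, "unit_price": 1.50, "delivery_point": "any"},
        {"intervention_id": "X1", "item": "visit", "category": "service_delivery",
         "quantity_per_case": _TOY_X1["contacts"], "unit_price": None, "delivery_point": "any"},
        {"intervention_id": "X2", "item": "toy drug B", "category": "drug",
         "quantity_per_case": 1, "unit_price": 2.00, "delivery_point": "any"},
        {"intervention_id": "X2", "item": "visit", "category": "service_delivery",
         "quantity_per_case": _TOY_X2["contacts"], "unit_price": None, "delivery_point": "any"},
    ]).to_csv(out_dir / "ingredients.csv", index=False)

    pd.DataFrame([
        {"country_id": cid, "level": level, "unit_cost": cost}
        for cid, _, _, _, _, h, p, c, _, _ in _TOY_COUNTRIES
        for level, cost in (("hospital", h), ("primary", p), ("community", c))
    ]).to_csv(out_dir / "unit_costs.csv", index=False)

    pd.DataFrame([
        {"activity_id": "mgmt", "category": "management", "level": "national",
         "scaling_driver": "per_country_year", "item": "coordination",
         "quantity": 1, "unit_price": _TOY_MGMT},
        {"activity_id": "training", "category": "training", "level": "facility",
         "scaling_driver": "per_facility", "item": "per diems",
         "quantity": 20, "unit_price": _TOY_TRAINING / 20},
        {"activity_id": "iec", "category": "IEC", "level": "national",
         "scaling_driver": "per_population", "item": "leaflets per 1000 adolescents",
         "quantity": 1000, "unit_price": _TOY_IEC / 1000},
    ]).to_csv(out_dir / "programme_activities.csv", index=False)

    pd.DataFrame([
        {"country_id": cid, "n_districts": nd, "n_facilities": nf}
        for cid, _, _, _, _, _, _, _, nd, nf in _TOY_COUNTRIES
    ]).to_csv(out_dir / "drivers.csv", index=False)

    (out_dir / "settings.yaml").write_text(yaml.safe_dump({
        "schema_version": "1", "n_countries": 2, "anchor_year": 2010,
        "annualization_years": 5, "seed": 0,
    }, sort_keys=True))

    return load_config(out_dir), expected_toy_cube(baseline_equals_target)
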