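"""Ingredients-based costing engine.

Cost per case = sum over ingredient lines of quantity x unit price. Two
kinds of lines exist: commodity lines (drugs, vaccines, laboratory tests,
medical supplies) priced globally per item, and service-delivery lines
(visits, bed-days, outreach contacts) priced per country and delivery level
and weighted by the intervention's delivery-point shares. Intervention
scale-up cost for a country-year is the incremental number of cases (the
population in need times the incremental coverage) times the cost per case.

Programme-activity costs (management, training, supervision, IEC,
infrastructure & equipment) are not tied to individual cases: they scale
with fixed driver counts (per country-year, per district, per facility),
except IEC which scales with the adolescent population of the year.

All amounts are constant 2008 US dollars; the cost cube is a tidy table of
(country, item, year, cost category, amount) cells that is additive under
any marginal aggregation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .coverage import CoverageTrajectory, incremental_coverage
from .errors import ValidationError
from .need import NeedEstimate
from .registry import Country, CostedIn, InterventionSpec

CUBE_COLUMNS = ["country_id", "item_id", "item_kind", "year", "cost_category", "amount"]


class IngredientCategory(str, Enum):
    drug = "drug"
    lab_test = "lab_test"
    medical_supply = "medical_supply"
    service_delivery = "service_delivery"


class CostCategory(str, Enum):
    commodities = "commodities"
    service_delivery = "service_delivery"
    programme = "programme"


class ActivityCategory(str, Enum):
    management = "management"
    training = "training"
    supervision = "supervision"
    IEC = "IEC"
    infrastructure_equipment = "infrastructure_equipment"


class ScalingDriver(str, Enum):
    per_country_year = "per_country_year"
    per_district = "per_district"
    per_facility = "per_facility"
    per_population = "per_population"


class ActivityLevel(str, Enum):
    national = "national"
    district = "district"
    facility = "facility"
    community = "community"


@dataclass(frozen=True)
class IngredientLine:
    intervention_id: str
    item: str
    category: IngredientCategory
    quantity_per_case: float
    unit_price: float | None = None  # None for service lines: priced per country/level
    delivery_point: str = "any"

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", IngredientCategory(self.category))
        if self.quantity_per_case < 0:
            raise ValidationError(f"negative quantity on {self.intervention_id}/{self.item}")
        if self.unit_price is not None and self.unit_price < 0:
            raise ValidationError(f"negative price on {self.intervention_id}/{self.item}")


@dataclass(frozen=True)
class ProgrammeActivitySpec:
    activity_id: str
    category: ActivityCategory
    level: ActivityLevel
    scaling_driver: ScalingDriver
    #: (item, quantity, unit price); for per_population activities the
    #: quantity is per 1,000 adolescents per year.
    components: tuple[tuple[str, float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", ActivityCategory(self.category))
        object.__setattr__(self, "level", ActivityLevel(self.level))
        object.__setattr__(self, "scaling_driver", ScalingDriver(self.scaling_driver))
        if (
            self.scaling_driver is ScalingDriver.per_population
            and self.category is not ActivityCategory.IEC
        ):
            raise ValidationError(
                f"{self.activity_id}: only IEC activities may scale per_population"
            )


@dataclass(frozen=True)
class CostPerCase:
    """US$ per treated case, split by operative cost category."""

    commodities: float
    service_delivery: float

    @property
    def total(self) -> float:
        return self.commodities + self.service_delivery


def cost_per_case(
    spec: InterventionSpec,
    ingredients: Sequence[IngredientLine],
    unit_costs: Mapping[str, float],
) -> CostPerCase:
    """Cost of delivering one case of an intervention in one country.

    ``unit_costs`` maps delivery level -> country-specific price of one
    service contact at that level. Every level with a positive delivery
    share must be priced; commodity lines carry their own global price.
    """
    commodities = 0.0
    service = 0.0
    for line in ingredients:
        if line.intervention_id != spec.intervention_id:
            continue
        if line.category is IngredientCategory.service_delivery:
            for level, share in spec.delivery_shares.items():
                if share <= 0.0:
                    continue
                if level not in unit_costs:
                    raise ValidationError(
                        f"missing service unit cost for level {level!r} required by "
                        f"{spec.intervention_id}"
                    )
                service += share * line.quantity_per_case * unit_costs[level]
        else:
            if line.unit_price is None:
                raise ValidationError(
                    f"commodity line {spec.intervention_id}/{line.item} has no price"
                )
            commodities += line.quantity_per_case * line.unit_price
    return CostPerCase(commodities=commodities, service_delivery=service)


def intervention_cost(
    country: Country,
    spec: InterventionSpec,
    year: int,
    need: NeedEstimate,
    traj: CoverageTrajectory,
    cpc: CostPerCase,
) -> list[dict]:
    """Cube records for one country x intervention x year.

    Incremental cases = persons in need x incremental coverage; cost records
    split the case cost into commodities and service delivery. Countries
    excluded from the maternity model yield no records for maternity-model
    interventions.
    """
    if (need.country_id, need.intervention_id) != (country.country_id, spec.intervention_id):
        raise ValidationError("need estimate does not match country/intervention")
    if (traj.country_id, traj.intervention_id) != (country.country_id, spec.intervention_id):
        raise ValidationError("trajectory does not match country/intervention")
    if need.year != year:
        raise ValidationError(f"need estimate is for {need.year}, not {year}")
    if spec.costed_in is CostedIn.maternity_model and country.excluded_from_maternity:
        return []
    cases = need.persons_in_need * incremental_coverage(traj, year)
    return [
        {
            "country_id": country.country_id,
            "item_id": spec.intervention_id,
            "item_kind": "intervention",
            "year": year,
            "cost_category": CostCategory.commodities.value,
            "amount": cases * cpc.commodities,
        },
        {
            "country_id": country.country_id,
            "item_id": spec.intervention_id,
            "item_kind": "intervention",
            "year": year,
            "cost_category": CostCategory.service_delivery.value,
            "amount": cases * cpc.service_delivery,
        },
    ]


def programme_cost(
    country: Country,
    activity: ProgrammeActivitySpec,
    year: int,
    drivers: Mapping[str, float],
    adol_population: float,
) -> list[dict]:
    """Cube records for one country x programme activity x year.

    The component subtotal is multiplied by the activity's driver: 1 for
    per-country-year activities, the district or facility count otherwise,
    and (adolescent population / 1000) for IEC. Countries excluded from the
    programme-activity costing yield no records.
    """
    if country.excluded_from_programme:
        return []
    subtotal = sum(q * p for _, q, p in activity.components)
    driver = activity.scaling_driver
    if driver is ScalingDriver.per_country_year:
        multiplier = 1.0
    elif driver is ScalingDriver.per_district:
        if "n_districts" not in drivers:
            raise ValidationError(f"missing n_districts for {country.country_id}")
        multiplier = float(drivers["n_districts"])
    elif driver is ScalingDriver.per_facility:
        if "n_facilities" not in drivers:
            raise ValidationError(f"missing n_facilities for {country.country_id}")
        multiplier = float(drivers["n_facilities"])
    elif driver is ScalingDriver.per_population:
        multiplier = adol_population / 1000.0
    else:  # pragma: no cover
        raise ValidationError(f"unknown scaling driver {driver}")
    return [
        {
            "country_id": country.country_id,
            "item_id": activity.activity_id,
            "item_kind": "programme_activity",
            "year": year,
            "cost_category": CostCategory.programme.value,
            "amount": subtotal * multiplier,
        }
    ]


def make_cube(records: Iterable[dict]) -> pd.DataFrame:
    """Assemble cube records into the canonical tidy DataFrame."""
    df = pd.DataFrame(list(records), columns=CUBE_COLUMNS)
    if (df["amount"] < 0).any():
        bad = df[df["amount"] < 0].iloc[0]
        raise ValidationError(f"negative cube cell: {bad.to_dict()}")
    return df.sort_values(CUBE_COLUMNS[:5], kind="mergesort").reset_index(drop=True)


def cube_total(cube: pd.DataFrame) -> float:
    """Grand total of a cost cube in US$."""
    return float(cube["amount"].sum())
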