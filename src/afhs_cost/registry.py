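"""Country and intervention registry.

Loads and validates the configuration tables that parameterize the costing
model: the 74-country registry (WHO region, adolescent population, HIV
prevalence, sexual-activity rates, model flags), the 19 costable service
interventions with their population-in-need rules, coverage ranges and
delivery-point shares, and the 20 characteristics of adolescent-friendly
health services grouped under the five quality-of-care dimensions.

Fractions are stored as fractions in [0, 1]; the CSV fixtures carry the
percentage values of the source tables (period decimals) and are converted
on load. Adolescent populations are stored as persons (fixtures are in
thousands).
"""
from __future__ import annotations

import logging
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pydantic

from .errors import IntegrityError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

#: Fields that may be filled from regional / global averages.
IMPUTABLE_FIELDS = (
    "hiv_prev_boys",
    "hiv_prev_girls",
    "sex_active_10_14_boys",
    "sex_active_10_14_girls",
    "sex_active_15_19_boys",
    "sex_active_15_19_girls",
)


class WhoRegion(str, Enum):
    AFR_D = "AFR_D"
    AFR_E = "AFR_E"
    AMR_B = "AMR_B"
    AMR_D = "AMR_D"
    EMR_D = "EMR_D"
    EUR_B = "EUR_B"
    SEAR_B = "SEAR_B"
    SEAR_D = "SEAR_D"
    WPR_B = "WPR_B"


class IncomeGroup(str, Enum):
    low = "low"
    middle = "middle"


class ImputationFlag(str, Enum):
    observed = "observed"
    regional_avg = "regional_avg"
    global_avg = "global_avg"


class Package(str, Enum):
    preventive_essential = "preventive_essential"
    preventive_expanded = "preventive_expanded"
    curative_essential = "curative_essential"
    curative_expanded = "curative_expanded"


class NeedBasis(str, Enum):
    all_adolescents = "all_adolescents"
    female_adolescents = "female_adolescents"
    sexually_active = "sexually_active"
    hiv_positive = "hiv_positive"
    condition_share = "condition_share"


class SexFilter(str, Enum):
    both = "both"
    female = "female"


class CostedIn(str, Enum):
    main_model = "main_model"
    maternity_model = "maternity_model"


class QualityDimension(str, Enum):
    equitable = "equitable"
    accessible = "accessible"
    acceptable = "acceptable"
    appropriate = "appropriate"
    effective = "effective"


DELIVERY_POINTS = ("hospital", "primary", "community")


class Country(pydantic.BaseModel):
    """One registry row: demography, epidemiology and model flags."""

    model_config = pydantic.ConfigDict(frozen=True)

    country_id: str
    name: str
    who_region: WhoRegion
    income_group: IncomeGroup
    adol_pop_2010: float = pydantic.Field(gt=0, description="persons aged 10-19")
    total_pop_2010: float = pydantic.Field(gt=0, description="persons, all ages")
    pop_growth_rate: float = pydantic.Field(gt=-1.0, description="fraction/year")
    hiv_prev_boys: float | None = pydantic.Field(default=None, ge=0, le=1)
    hiv_prev_girls: float | None = pydantic.Field(default=None, ge=0, le=1)
    sex_active_10_14_boys: float | None = pydantic.Field(default=None, ge=0, le=1)
    sex_active_10_14_girls: float | None = pydantic.Field(default=None, ge=0, le=1)
    sex_active_15_19_boys: float | None = pydantic.Field(default=None, ge=0, le=1)
    sex_active_15_19_girls: float | None = pydantic.Field(default=None, ge=0, le=1)
    imputation_flags: dict[str, ImputationFlag] = pydantic.Field(default_factory=dict)
    excluded_from_maternity: bool = False
    excluded_from_programme: bool = False
    abortion_legal: bool = True
    harm_reduction_permitted: bool = True


class InterventionSpec(pydantic.BaseModel):
    """One costable service intervention (a lettered sub-row of the catalogue)."""

    model_config = pydantic.ConfigDict(frozen=True)

    intervention_id: str
    name: str
    group: str
    package: Package
    need_basis: NeedBasis
    need_share_range: tuple[float, float]
    coverage_range: tuple[float, float]
    target_coverage: float = pydantic.Field(ge=0, le=1)
    delivery_shares: dict[str, float]
    sex_filter: SexFilter = SexFilter.both
    requires_abortion_legal: bool = False
    requires_harm_reduction: bool = False
    costed_in: CostedIn = CostedIn.main_model

    @pydantic.field_validator("need_share_range", "coverage_range")
    @classmethod
    def _check_range(cls, v: tuple[float, float]) -> tuple[float, float]:
        lo, hi = v
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"range [{lo}, {hi}] must satisfy 0 <= lo <= hi <= 1")
        return v

    @pydantic.field_validator("delivery_shares")
    @classmethod
    def _check_shares(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(DELIVERY_POINTS)
        if unknown:
            raise ValueError(f"unknown delivery points {sorted(unknown)}")
        total = sum(v.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"delivery shares sum to {total}, expected 1")
        if any(s < 0 for s in v.values()):
            raise ValueError("delivery shares must be non-negative")
        return v


class AfhsCharacteristic(pydantic.BaseModel):
    """One of the 20 adolescent-friendly service characteristics."""

    model_config = pydantic.ConfigDict(frozen=True)

    number: int = pydantic.Field(ge=1, le=20)
    dimension: QualityDimension
    text: str


def default_data_path(filename: str) -> Path:
    """Path of a packaged default configuration table."""
    return Path(str(resources.files("afhs_cost").joinpath("data", filename)))


_COUNTRY_PCT_COLS = {f + "_pct": f for f in IMPUTABLE_FIELDS}
_COUNTRY_REQUIRED = [
    "country_id", "name", "who_region", "income_group",
    "adol_pop_2010_thousands", "total_pop_2010_thousands", "pop_growth_rate",
    *_COUNTRY_PCT_COLS,
    "excluded_from_maternity", "excluded_from_programme",
    "abortion_legal", "harm_reduction_permitted",
]


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"configuration file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise IntegrityError(f"{path} is empty") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} is missing required columns {missing}")
    return df


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in {"true", "1", "yes"}


def load_country_table(
    path: str | Path,
    schema_version: str = SCHEMA_VERSION,
    expected_count: int = 74,
) -> list[Country]:
    """Load and validate the country registry.

    Percentage columns are converted to fractions; a blank cell becomes
    ``None`` (to be filled by :func:`impute_field`). Populations given in
    thousands are converted to persons. Raises :class:`IntegrityError` if the
    row count differs from ``expected_count`` (74 for the full registry) and
    :class:`ValidationError` naming the offending row/field for out-of-range
    values. No partial registry is ever returned.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    df = _read_csv(path, _COUNTRY_REQUIRED)
    if len(df) != expected_count:
        raise IntegrityError(
            f"{path}: expected {expected_count} countries, found {len(df)}"
        )
    countries: list[Country] = []
    for _, row in df.iterrows():
        fields: dict = {
            "country_id": row["country_id"],
            "name": row["name"],
            "who_region": row["who_region"],
            "income_group": row["income_group"],
            "adol_pop_2010": float(row["adol_pop_2010_thousands"]) * 1000.0,
            "total_pop_2010": float(row["total_pop_2010_thousands"]) * 1000.0,
            "pop_growth_rate": float(row["pop_growth_rate"]),
            "excluded_from_maternity": _as_bool(row["excluded_from_maternity"]),
            "excluded_from_programme": _as_bool(row["excluded_from_programme"]),
            "abortion_legal": _as_bool(row["abortion_legal"]),
            "harm_reduction_permitted": _as_bool(row["harm_reduction_permitted"]),
        }
        flags: dict[str, ImputationFlag] = {}
        for col, field in _COUNTRY_PCT_COLS.items():
            raw = row[col]
            if pd.isna(raw):
                fields[field] = None
            else:
                fields[field] = float(raw) / 100.0
            src_col = f"{field}_src"
            if src_col in df.columns and not pd.isna(row.get(src_col)):
                flags[field] = ImputationFlag(row[src_col])
            else:
                flags[field] = ImputationFlag.observed
        fields["imputation_flags"] = flags
        try:
            countries.append(Country(**fields))
        except pydantic.ValidationError as exc:
            raise ValidationError(
                f"{path}: invalid country row {row['country_id']!r}: {exc}"
            ) from exc
    if len({c.country_id for c in countries}) != len(countries):
        raise IntegrityError(f"{path}: duplicate country_id values")
    n_imputed = sum(
        1 for c in countries for f in IMPUTABLE_FIELDS
        if c.imputation_flags.get(f) != ImputationFlag.observed
    )
    logger.info("loaded %d countries (%d imputed field values)", len(countries), n_imputed)
    return countries


def impute_field(countries: Sequence[Country], field: str) -> list[Country]:
    """Fill missing values of ``field`` from observed same-region values.

    A missing value receives the adolescent-population-weighted mean of the
    observed values in the country's WHO region; if the region has no
    observed value, the population-weighted global mean over all countries
    is used instead. Imputation flags are updated to ``regional_avg`` /
    ``global_avg``. Countries with a value present are returned unchanged,
    so the operation is idempotent.
    """
    if field not in IMPUTABLE_FIELDS:
        raise ValidationError(f"unknown imputable field {field!r}")
    observed = [
        c for c in countries
        if getattr(c, field) is not None
        and c.imputation_flags.get(field) == ImputationFlag.observed
    ]
    if not observed:
        raise ValidationError(f"no observed values of {field!r} anywhere")

    def weighted_mean(group: Iterable[Country]) -> float | None:
        group = list(group)
        if not group:
            return None
        weight = sum(c.adol_pop_2010 for c in group)
        return sum(getattr(c, field) * c.adol_pop_2010 for c in group) / weight

    global_mean = weighted_mean(observed)
    result: list[Country] = []
    for c in countries:
        if getattr(c, field) is not None:
            result.append(c)
            continue
        regional = weighted_mean(o for o in observed if o.who_region == c.who_region)
        if regional is not None:
            value, flag = regional, ImputationFlag.regional_avg
        else:
            value, flag = global_mean, ImputationFlag.global_avg
        logger.info(
            "imputed %s for %s: %.6f (%s)", field, c.country_id, value, flag.value
        )
        result.append(
            c.model_copy(
                update={
                    field: value,
                    "imputation_flags": {**c.imputation_flags, field: flag},
                }
            )
        )
    return result


_INTERVENTION_REQUIRED = [
    "intervention_id", "name", "group", "package", "need_basis",
    "need_lo", "need_hi", "coverage_lo", "coverage_hi", "target_coverage",
    "share_hospital", "share_primary", "share_community",
    "sex_filter", "requires_abortion_legal", "requires_harm_reduction", "costed_in",
]


def load_intervention_table(path: str | Path) -> list[InterventionSpec]:
    """Load the intervention catalogue (19 service rows in 8 groups).

    Delivery-point shares must sum to 1 per row; the scale-up target is 95%
    for every intervention except opioid substitution therapy (50%).
    """
    df = _read_csv(path, _INTERVENTION_REQUIRED)
    specs: list[InterventionSpec] = []
    for _, row in df.iterrows():
        try:
            specs.append(
                InterventionSpec(
                    intervention_id=str(row["intervention_id"]),
                    name=row["name"],
                    group=row["group"],
                    package=row["package"],
                    need_basis=row["need_basis"],
                    need_share_range=(float(row["need_lo"]), float(row["need_hi"])),
                    coverage_range=(float(row["coverage_lo"]), float(row["coverage_hi"])),
                    target_coverage=float(row["target_coverage"]),
                    delivery_shares={
                        "hospital": float(row["share_hospital"]),
                        "primary": float(row["share_primary"]),
                        "community": float(row["share_community"]),
                    },
                    sex_filter=row["sex_filter"],
                    requires_abortion_legal=_as_bool(row["requires_abortion_legal"]),
                    requires_harm_reduction=_as_bool(row["requires_harm_reduction"]),
                    costed_in=row["costed_in"],
                )
            )
        except pydantic.ValidationError as exc:
            raise ValidationError(
                f"{path}: invalid intervention row {row['intervention_id']!r}: {exc}"
            ) from exc
    ids = [s.intervention_id for s in specs]
    if len(set(ids)) != len(ids):
        raise IntegrityError(f"{path}: duplicate intervention_id values")
    logger.info("loaded %d interventions", len(specs))
    return specs


def load_characteristics(path: str | Path) -> list[AfhsCharacteristic]:
    """Load the 20 adolescent-friendly service characteristics."""
    df = _read_csv(path, ["number", "dimension", "text"])
    if len(df) != 20:
        raise IntegrityError(f"{path}: expected 20 characteristics, found {len(df)}")
    chars = [
        AfhsCharacteristic(number=int(r["number"]), dimension=r["dimension"], text=r["text"])
        for _, r in df.iterrows()
    ]
    if sorted(c.number for c in chars) != list(range(1, 21)):
        raise IntegrityError(f"{path}: characteristic numbers must be 1..20")
    return chars


def load_default_registry() -> tuple[list[Country], list[InterventionSpec], list[AfhsCharacteristic]]:
    """Load the packaged country, intervention and characteristics tables."""
    return (
        load_country_table(default_data_path("countries.csv")),
        load_intervention_table(default_data_path("interventions.csv")),
        load_characteristics(default_data_path("characteristics.csv")),
    )
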