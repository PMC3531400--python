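"""Population projection and population-in-need estimation.

The population eligible for each intervention is derived from the 2010
adolescent population of a country, projected forward with constant
geometric growth (epidemiological risk is held constant over the horizon,
so need moves only with demography), split into sex and age-band slices,
and weighted by the intervention's need basis: all adolescents, female
adolescents, the sexually active (band-specific rates), or HIV-positive
adolescents (sex-specific prevalence). A per-country need share within the
catalogue's stated range converts the eligible population into the
population in need. Fractional persons are carried as reals throughout;
rounding belongs in report formatting only.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .errors import ValidationError
from .registry import Country, InterventionSpec, NeedBasis, SexFilter


class Sex(str, Enum):
    male = "male"
    female = "female"
    both = "both"


class AgeBand(str, Enum):
    b10_14 = "10_14"
    b15_19 = "15_19"
    b10_19 = "10_19"


@dataclass(frozen=True)
class PopulationSlice:
    country_id: str
    year: int
    sex: Sex
    age_band: AgeBand
    persons: float

    def __post_init__(self) -> None:
        if self.persons < 0:
            raise ValidationError(f"negative population slice: {self}")


@dataclass(frozen=True)
class NeedEstimate:
    country_id: str
    intervention_id: str
    year: int
    persons_in_need: float
    basis_used: NeedBasis


#: Default sex and age-band shares of the 10-19 population (the source
#: country table reports only 10-19 totals; an even split is the documented
#: modelling default and can be overridden per country).
DEFAULT_SEX_SHARES = {Sex.male: 0.5, Sex.female: 0.5}
DEFAULT_AGE_SHARES = {AgeBand.b10_14: 0.5, AgeBand.b15_19: 0.5}


def project_population(base: PopulationSlice, growth_rate: float, year: int) -> PopulationSlice:
    """Project a population slice forward with constant geometric growth.

    ``persons(year) = persons(base.year) * (1 + growth_rate)**(year - base.year)``.
    Back-projection is not supported.
    """
    if year < base.year:
        raise ValidationError(f"cannot project backwards from {base.year} to {year}")
    if growth_rate <= -1:
        raise ValidationError(f"growth rate {growth_rate} must exceed -1")
    factor = (1.0 + growth_rate) ** (year - base.year)
    return PopulationSlice(base.country_id, year, base.sex, base.age_band, base.persons * factor)


def split_population(
    total: PopulationSlice,
    sex_shares: dict[Sex, float] | None = None,
    age_shares: dict[AgeBand, float] | None = None,
) -> list[PopulationSlice]:
    """Split a both-sexes 10-19 slice into four sex x age-band slices.

    The four slices sum exactly to the input count. For whole-person inputs
    the counts are reconciled to integers by the largest-remainder rule;
    fractional inputs are split proportionally with the residual assigned to
    the last slice.
    """
    sex_shares = dict(sex_shares or DEFAULT_SEX_SHARES)
    age_shares = dict(age_shares or DEFAULT_AGE_SHARES)
    for name, shares in (("sex", sex_shares), ("age", age_shares)):
        s = sum(shares.values())
        if abs(s - 1.0) > 1e-9:
            raise ValidationError(f"{name} shares sum to {s}, expected 1")
        if any(v < 0 for v in shares.values()):
            raise ValidationError(f"{name} shares must be non-negative")

    keys = [(sex, band) for sex in (Sex.male, Sex.female)
            for band in (AgeBand.b10_14, AgeBand.b15_19)]
    raw = [total.persons * sex_shares[sex] * age_shares[band] for sex, band in keys]
    if float(total.persons).is_integer():
        floors = [math.floor(x) for x in raw]
        leftover = round(total.persons - sum(floors))
        order = sorted(range(4), key=lambda i: raw[i] - floors[i], reverse=True)
        for i in order[:leftover]:
            floors[i] += 1
        parts = [float(f) for f in floors]
    else:
        parts = raw[:]
        parts[-1] = total.persons - sum(parts[:-1])
    return [
        PopulationSlice(total.country_id, total.year, sex, band, p)
        for (sex, band), p in zip(keys, parts)
    ]


def _band_rates(country: Country, sex: Sex) -> dict[AgeBand, float]:
    suffix = "boys" if sex is Sex.male else "girls"
    return {
        AgeBand.b10_14: getattr(country, f"sex_active_10_14_{suffix}"),
        AgeBand.b15_19: getattr(country, f"sex_active_15_19_{suffix}"),
    }


def eligible_population(
    country: Country,
    spec: InterventionSpec,
    year: int,
    sex_shares: dict[Sex, float] | None = None,
    age_shares: dict[AgeBand, float] | None = None,
) -> float:
    """Sex/age-eligible population for an intervention before the need share.

    Applies the intervention's sex filter and need basis (sexual-activity
    weighting for ``sexually_active``, HIV prevalence for ``hiv_positive``)
    to the projected sex x band slices of the country-year.
    """
    base = PopulationSlice(country.country_id, 2010, Sex.both, AgeBand.b10_19,
                           country.adol_pop_2010)
    projected = project_population(base, country.pop_growth_rate, year)
    slices = split_population(projected, sex_shares, age_shares)
    sexes = (Sex.female,) if spec.sex_filter is SexFilter.female else (Sex.male, Sex.female)
    picked = [s for s in slices if s.sex in sexes]

    basis = spec.need_basis
    if basis in (NeedBasis.all_adolescents, NeedBasis.female_adolescents,
                 NeedBasis.condition_share):
        return sum(s.persons for s in picked)
    if basis is NeedBasis.sexually_active:
        total = 0.0
        for s in picked:
            rate = _band_rates(country, s.sex)[s.age_band]
            if rate is None:
                raise ValidationError(
                    f"missing sexual-activity rate for {country.country_id} "
                    f"{s.sex.value} {s.age_band.value}"
                )
            total += s.persons * rate
        return total
    if basis is NeedBasis.hiv_positive:
        total = 0.0
        for s in picked:
            prev = country.hiv_prev_boys if s.sex is Sex.male else country.hiv_prev_girls
            if prev is None:
                raise ValidationError(
                    f"missing HIV prevalence for {country.country_id} {s.sex.value}"
                )
            total += s.persons * prev
        return total
    raise ValidationError(f"unknown need basis {basis}")  # pragma: no cover


def population_in_need(
    country: Country,
    spec: InterventionSpec,
    year: int,
    need_share: float,
    sex_shares: dict[Sex, float] | None = None,
    age_shares: dict[AgeBand, float] | None = None,
) -> NeedEstimate:
    """Population in need for a country x intervention x year.

    ``persons_in_need = eligible population x need share``, where the need
    share must lie within the catalogue's stated range for the intervention.
    A country where a legally required precondition (abortion legality, harm
    reduction) does not hold contributes zero need.
    """
    lo, hi = spec.need_share_range
    if not (lo - 1e-12 <= need_share <= hi + 1e-12):
        raise ValidationError(
            f"need share {need_share} for {country.country_id}/{spec.intervention_id} "
            f"outside catalogue range [{lo}, {hi}]"
        )
    if (spec.requires_abortion_legal and not country.abortion_legal) or (
        spec.requires_harm_reduction and not country.harm_reduction_permitted
    ):
        persons = 0.0
    else:
        persons = eligible_population(country, spec, year, sex_shares, age_shares) * need_share
    return NeedEstimate(country.country_id, spec.intervention_id, year, persons, spec.need_basis)
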