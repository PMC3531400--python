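"""Population projection, splitting, and population-in-need rules."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afhs_cost import (
    AgeBand,
    Country,
    InterventionSpec,
    PopulationSlice,
    Sex,
    ValidationError,
    eligible_population,
    population_in_need,
    project_population,
    split_population,
)


def make_country(**over):
    base = dict(
        country_id="TST", name="Testland", who_region="AFR_D", income_group="low",
        adol_pop_2010=1_000_000, total_pop_2010=5_000_000, pop_growth_rate=0.02,
        hiv_prev_boys=0.01, hiv_prev_girls=0.02,
        sex_active_10_14_boys=0.10, sex_active_10_14_girls=0.12,
        sex_active_15_19_boys=0.40, sex_active_15_19_girls=0.50,
    )
    base.update(over)
    return Country(**base)


def make_spec(**over):
    base = dict(
        intervention_id="T1", name="test", group="g", package="preventive_essential",
        need_basis="all_adolescents", need_share_range=(0.0, 1.0),
        coverage_range=(0.0, 0.95), target_coverage=0.95,
        delivery_shares={"hospital": 0.0, "primary": 1.0, "community": 0.0},
    )
    base.update(over)
    return InterventionSpec(**base)


def slice_(persons, year=2010, sex=Sex.both, band=AgeBand.b10_19):
    return PopulationSlice("TST", year, sex, band, persons)


class TestProjection:
    def test_geometric_growth(self):
        out = project_population(slice_(100), 0.02, 2012)
        assert out.persons == pytest.approx(104.04)
        assert out.year == 2012

    def test_zero_growth_is_identity(self):
        for year in (2010, 2013, 2015):
            assert project_population(slice_(100), 0.0, year).persons == 100

    def test_multi_year_equals_iterated_single_years(self):
        rate = 0.0137
        direct = project_population(slice_(9_213_000), rate, 2015)
        stepped = slice_(9_213_000)
        for year in range(2011, 2016):
            stepped = project_population(stepped, rate, year)
        assert direct.persons == pytest.approx(stepped.persons, rel=1e-12)
        assert direct.persons == pytest.approx(9_213_000 * 1.0137**5)

    def test_no_back_projection(self):
        with pytest.raises(ValidationError):
            project_population(slice_(100, year=2012), 0.02, 2011)


class TestSplit:
    def test_symmetric_split(self):
        parts = split_population(slice_(1000))
        assert [p.persons for p in parts] == [250, 250, 250, 250]

    def test_asymmetric_split_reconciles_exactly(self):
        parts = split_population(
            slice_(1000),
            sex_shares={Sex.male: 0.52, Sex.female: 0.48},
        )
        assert sorted(p.persons for p in parts) == [240, 240, 260, 260]
        assert sum(p.persons for p in parts) == 1000

    def test_largest_remainder_on_awkward_shares(self):
        parts = split_population(
            slice_(100),
            sex_shares={Sex.male: 1 / 3, Sex.female: 2 / 3},
            age_shares={AgeBand.b10_14: 1 / 3, AgeBand.b15_19: 2 / 3},
        )
        assert sum(p.persons for p in parts) == 100
        assert all(float(p.persons).is_integer() for p in parts)

    def test_invalid_shares_rejected(self):
        with pytest.raises(ValidationError):
            split_population(slice_(1000), sex_shares={Sex.male: 0.5, Sex.female: 0.4})

    @settings(max_examples=100, derandomize=True)
    @given(
        total=st.integers(0, 10**9),
        ms=st.floats(0.01, 0.99, allow_nan=False),
        a14=st.floats(0.01, 0.99, allow_nan=False),
    )
    def test_split_conserves_total(self, total, ms, a14):
        parts = split_population(
            slice_(total),
            sex_shares={Sex.male: ms, Sex.female: 1 - ms},
            age_shares={AgeBand.b10_14: a14, AgeBand.b15_19: 1 - a14},
        )
        assert sum(p.persons for p in parts) == total
        assert all(p.persons >= 0 for p in parts)


class TestPopulationInNeed:
    def test_female_share_rule(self):
        # 4% of female adolescents on a 1,000,000 pool -> 500,000 girls -> 20,000
        country = make_country(pop_growth_rate=0.0)
        spec = make_spec(need_basis="female_adolescents", sex_filter="female",
                         need_share_range=(0.02, 0.04))
        est = population_in_need(country, spec, 2011, 0.04)
        assert est.persons_in_need == pytest.approx(20_000)

    def test_zero_prevalence_means_zero_need(self):
        country = make_country(hiv_prev_boys=0.0, hiv_prev_girls=0.0)
        spec = make_spec(need_basis="hiv_positive", need_share_range=(0.0, 1.0))
        assert population_in_need(country, spec, 2013, 0.5).persons_in_need == 0.0

    def test_abortion_service_zero_where_illegal(self):
        country = make_country(abortion_legal=False)
        spec = make_spec(need_basis="female_adolescents", sex_filter="female",
                         requires_abortion_legal=True, need_share_range=(0.01, 0.04))
        assert population_in_need(country, spec, 2012, 0.02).persons_in_need == 0.0

    def test_harm_reduction_zero_where_not_permitted(self):
        country = make_country(harm_reduction_permitted=False)
        spec = make_spec(need_basis="condition_share", requires_harm_reduction=True,
                         need_share_range=(0.0, 0.01))
        assert population_in_need(country, spec, 2012, 0.005).persons_in_need == 0.0

    def test_sexually_active_uses_band_specific_rates(self):
        country = make_country(pop_growth_rate=0.0)
        spec = make_spec(need_basis="sexually_active")
        est = population_in_need(country, spec, 2011, 1.0)
        expected = 250_000 * (0.10 + 0.40 + 0.12 + 0.50)
        assert est.persons_in_need == pytest.approx(expected)

    def test_need_share_outside_range_names_range(self):
        spec = make_spec(need_share_range=(0.02, 0.04))
        with pytest.raises(ValidationError, match=r"\[0.02, 0.04\]"):
            population_in_need(make_country(), spec, 2011, 0.10)

    def test_need_never_exceeds_eligible_population(self):
        country = make_country()
        for basis, sex_filter in [("all_adolescents", "both"),
                                  ("female_adolescents", "female"),
                                  ("sexually_active", "both"),
                                  ("hiv_positive", "both")]:
            spec = make_spec(need_basis=basis, sex_filter=sex_filter)
            pin = population_in_need(country, spec, 2015, 1.0).persons_in_need
            pop_2015 = country.adol_pop_2010 * 1.02**5
            assert pin <= pop_2015 + 1e-6

    @settings(max_examples=50, derandomize=True)
    @given(
        pop=st.floats(1e3, 1e8),
        share=st.floats(0, 1),
        prev=st.floats(0, 1),
        growth=st.floats(0.0, 0.05),
    )
    def test_monotone_in_population_share_prevalence_and_year(self, pop, share, prev, growth):
        spec = make_spec(need_basis="hiv_positive")
        c = make_country(adol_pop_2010=pop, hiv_prev_boys=prev, hiv_prev_girls=prev,
                         pop_growth_rate=growth)
        bigger_pop = make_country(adol_pop_2010=pop * 2, hiv_prev_boys=prev,
                                  hiv_prev_girls=prev, pop_growth_rate=growth)
        higher_prev = make_country(adol_pop_2010=pop, hiv_prev_boys=min(1, prev + 0.1),
                                   hiv_prev_girls=min(1, prev + 0.1), pop_growth_rate=growth)
        pin = population_in_need(c, spec, 2012, share).persons_in_need
        assert population_in_need(bigger_pop, spec, 2012, share).persons_in_need >= pin
        assert population_in_need(higher_prev, spec, 2012, share).persons_in_need >= pin
        assert population_in_need(c, spec, 2013, share).persons_in_need >= pin
        if share < 1:
            assert population_in_need(c, spec, 2012, min(1, share + 0.1)).persons_in_need >= pin


def test_eligible_population_requires_rates():
    country = make_country(sex_active_10_14_boys=None)
    spec = make_spec(need_basis="sexually_active")
    with pytest.raises(ValidationError, match="sexual-activity"):
        eligible_population(country, spec, 2012)
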