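"""Country registry, intervention catalogue and imputation."""
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afhs_cost import (
    Country,
    ImputationFlag,
    IntegrityError,
    ValidationError,
    impute_field,
    load_characteristics,
    load_country_table,
    load_intervention_table,
)
from afhs_cost.registry import default_data_path


def _mk(cid, region, pop, value, flag="observed"):
    return Country(
        country_id=cid, name=cid, who_region=region, income_group="low",
        adol_pop_2010=pop, total_pop_2010=5 * pop, pop_growth_rate=0.01,
        hiv_prev_boys=value,
        imputation_flags={"hiv_prev_boys": ImputationFlag(flag)},
    )


class TestCountryTable:
    def test_kenya_row_converted_to_persons_and_fractions(self, registry):
        countries, _, _ = registry
        kenya = next(c for c in countries if c.name == "Kenya")
        assert kenya.adol_pop_2010 == pytest.approx(9_213_000)
        assert kenya.hiv_prev_boys == pytest.approx(0.0117)
        assert kenya.sex_active_15_19_boys == pytest.approx(0.612)
        assert kenya.who_region.value == "AFR_E"

    def test_angola_sexual_activity_flagged_regional(self, registry):
        countries, _, _ = registry
        angola = next(c for c in countries if c.name == "Angola")
        assert angola.sex_active_10_14_boys == pytest.approx(0.0894)
        assert angola.imputation_flags["sex_active_10_14_boys"] is ImputationFlag.regional_avg
        assert angola.imputation_flags["hiv_prev_boys"] is ImputationFlag.observed

    def test_registry_cardinality_and_exclusions(self, registry):
        countries, _, chars = registry
        assert len(countries) == 74
        assert len(chars) == 20
        maternity_excluded = {c.name for c in countries if c.excluded_from_maternity}
        assert maternity_excluded == {
            "Botswana", "Democratic People's Republic of Korea",
            "Sao Tome and Principe", "Solomon Islands", "Turkmenistan", "Uzbekistan",
        }
        assert {c.name for c in countries if c.excluded_from_programme} == {"Somalia"}

    def test_income_split(self, registry):
        countries, _, _ = registry
        groups = pd.Series([c.income_group.value for c in countries]).value_counts()
        assert groups["low"] == 35 and groups["middle"] == 39

    def test_empty_file_is_integrity_error(self, tmp_path):
        p = tmp_path / "countries.csv"
        p.write_text("")
        with pytest.raises(IntegrityError):
            load_country_table(p)

    def test_wrong_count_is_integrity_error(self, tmp_path):
        df = pd.read_csv(default_data_path("countries.csv")).head(10)
        p = tmp_path / "countries.csv"
        df.to_csv(p, index=False)
        with pytest.raises(IntegrityError):
            load_country_table(p)  # expects 74
        assert len(load_country_table(p, expected_count=10)) == 10

    def test_fraction_out_of_range_names_row(self, tmp_path):
        df = pd.read_csv(default_data_path("countries.csv"))
        df.loc[df.country_id == "KEN", "hiv_prev_boys_pct"] = 150.0
        p = tmp_path / "countries.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValidationError, match="KEN"):
            load_country_table(p)

    def test_missing_column_is_schema_error(self, tmp_path):
        from afhs_cost import SchemaError
        df = pd.read_csv(default_data_path("countries.csv")).drop(columns=["who_region"])
        p = tmp_path / "countries.csv"
        df.to_csv(p, index=False)
        with pytest.raises(SchemaError, match="who_region"):
            load_country_table(p)


class TestInterventionTable:
    def test_delivery_shares_and_targets(self, registry):
        _, interventions, _ = registry
        assert len(interventions) == 19
        by_id = {s.intervention_id: s for s in interventions}
        anc = by_id["2a"]
        assert anc.delivery_shares == {"hospital": 0.90, "primary": 0.05, "community": 0.05}
        ost = by_id["6b"]
        assert ost.target_coverage == 0.50
        assert ost.delivery_shares["primary"] == 1.0
        htc = by_id["3"]
        assert htc.delivery_shares == {"hospital": 0.80, "primary": 0.20, "community": 0.0}
        assert by_id["7"].delivery_shares == {"hospital": 0.70, "primary": 0.20, "community": 0.10}
        for s in interventions:
            assert sum(s.delivery_shares.values()) == pytest.approx(1.0, abs=1e-9)
            if s.intervention_id != "6b":
                assert s.target_coverage == 0.95

    def test_bad_shares_rejected(self, tmp_path):
        df = pd.read_csv(default_data_path("interventions.csv"))
        df.loc[0, "share_primary"] = 0.8
        df.loc[0, "share_community"] = 0.3
        df.loc[0, "share_hospital"] = 0.0
        p = tmp_path / "interventions.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValidationError):
            load_intervention_table(p)

    def test_duplicate_id_rejected(self, tmp_path):
        df = pd.read_csv(default_data_path("interventions.csv"))
        df = pd.concat([df, df.head(1)])
        p = tmp_path / "interventions.csv"
        df.to_csv(p, index=False)
        with pytest.raises(IntegrityError):
            load_intervention_table(p)


class TestCharacteristics:
    def test_dimension_partition(self, registry):
        _, _, chars = registry
        counts = pd.Series([c.dimension.value for c in chars]).value_counts()
        assert counts.to_dict() == {
            "equitable": 3, "accessible": 5, "acceptable": 7,
            "appropriate": 1, "effective": 4,
        }

    def test_wrong_count_rejected(self, tmp_path):
        df = pd.read_csv(default_data_path("characteristics.csv")).head(19)
        p = tmp_path / "characteristics.csv"
        df.to_csv(p, index=False)
        with pytest.raises(IntegrityError):
            load_characteristics(p)


class TestImputation:
    def test_weighted_mean_from_region(self):
        countries = [
            _mk("A", "AFR_D", 1000, 0.10),
            _mk("B", "AFR_D", 3000, 0.20),
            _mk("C", "AFR_D", 500, None),
        ]
        out = impute_field(countries, "hiv_prev_boys")
        filled = next(c for c in out if c.country_id == "C")
        assert filled.hiv_prev_boys == pytest.approx((1000 * 0.10 + 3000 * 0.20) / 4000)
        assert filled.imputation_flags["hiv_prev_boys"] is ImputationFlag.regional_avg

    def test_region_without_observations_gets_global_mean(self):
        countries = [
            _mk("A", "AFR_D", 1000, 0.10),
            _mk("B", "AFR_E", 3000, 0.20),
            _mk("C", "EUR_B", 500, None),
        ]
        out = impute_field(countries, "hiv_prev_boys")
        filled = next(c for c in out if c.country_id == "C")
        assert filled.hiv_prev_boys == pytest.approx(0.175)
        assert filled.imputation_flags["hiv_prev_boys"] is ImputationFlag.global_avg

    def test_no_missing_is_identity(self):
        countries = [_mk("A", "AFR_D", 1000, 0.10), _mk("B", "AFR_D", 3000, 0.20)]
        assert impute_field(countries, "hiv_prev_boys") == countries

    def test_unknown_field_and_no_observations_rejected(self):
        with pytest.raises(ValidationError):
            impute_field([_mk("A", "AFR_D", 1000, 0.10)], "shoe_size")
        with pytest.raises(ValidationError):
            impute_field([_mk("A", "AFR_D", 1000, None)], "hiv_prev_boys")

    @settings(max_examples=50, derandomize=True)
    @given(
        values=st.lists(
            st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
            min_size=2, max_size=12,
        ),
        pops=st.lists(st.integers(1, 10_000_000), min_size=12, max_size=12),
        regions=st.lists(st.sampled_from(["AFR_D", "AFR_E", "EMR_D"]), min_size=12, max_size=12),
    )
    def test_imputation_idempotent_and_bounded(self, values, pops, regions):
        countries = [
            _mk(f"C{i}", regions[i], pops[i], v)
            for i, v in enumerate(values)
        ]
        observed = [v for v in values if v is not None]
        if not observed:
            return
        once = impute_field(countries, "hiv_prev_boys")
        twice = impute_field(once, "hiv_prev_boys")
        assert once == twice
        for c in once:
            assert min(observed) - 1e-12 <= c.hiv_prev_boys <= max(observed) + 1e-12
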