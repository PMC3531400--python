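"""Scenario runs, current-spending derivation and reporting aggregations.

``run_scenario`` executes the full pipeline — population in need, coverage
trajectory, cost per case, programme activities — for every eligible
country x intervention x year cell and returns a deterministic cost cube.
Running the model both from observed baselines (``incremental``) and from
0% coverage (``from_zero``) allows current spending on the service package
to be estimated as the cell-wise difference of the two cubes.

Reporting verbs aggregate the cube by year, WHO region, intervention group,
cost category and income group, and derive per-adolescent / per-capita
dollar figures.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import ModelConfig, load_config
from .costing import cost_per_case, cube_total, intervention_cost, make_cube, programme_cost
from .coverage import END_YEAR, START_YEAR, ScenarioMode, make_trajectory
from .errors import ValidationError
from .need import population_in_need

MODEL_YEARS = tuple(range(START_YEAR, END_YEAR + 1))

GROUPING_KEYS = ("year", "who_region", "intervention_group", "cost_category", "income_group")

#: Reporting label for programme-activity cube cells.
PROGRAMME_GROUP = "programme_activities"


@dataclass(frozen=True)
class ScenarioResult:
    mode: ScenarioMode
    cube: pd.DataFrame
    config: ModelConfig
    metadata: dict

    @property
    def total(self) -> float:
        return cube_total(self.cube)


def run_scenario(config: ModelConfig | str | Path, mode: ScenarioMode | str) -> ScenarioResult:
    """Run the costing pipeline for all eligible cells.

    Deterministic: the same configuration always yields the identical cube.
    Any validation error aborts the run with no partial output.
    """
    if not isinstance(config, ModelConfig):
        config = load_config(config)
    mode = ScenarioMode(mode)
    anchor = config.settings.anchor_year
    records: list[dict] = []

    for country in config.countries:
        unit_costs = config.unit_cost_map(country.country_id)
        for spec in config.interventions:
            cpc = cost_per_case(spec, config.ingredients, unit_costs)
            baseline = config.baseline(country.country_id, spec.intervention_id)
            traj = make_trajectory(country.country_id, spec, baseline, mode, anchor_year=anchor)
            share = config.need_share(country.country_id, spec.intervention_id)
            for year in MODEL_YEARS:
                need = population_in_need(country, spec, year, share)
                records.extend(intervention_cost(country, spec, year, need, traj, cpc))
        drivers = config.driver_map(country.country_id)
        for activity in config.activities:
            for year in MODEL_YEARS:
                adol_pop = country.adol_pop_2010 * (1.0 + country.pop_growth_rate) ** (year - 2010)
                records.extend(programme_cost(country, activity, year, drivers, adol_pop))

    cube = make_cube(records)
    metadata = {
        "mode": mode.value,
        "config_hash": config.config_hash,
        "seed": config.settings.seed,
        "anchor_year": anchor,
    }
    return ScenarioResult(mode=mode, cube=cube, config=config, metadata=metadata)


def current_spending(inc: ScenarioResult, fz: ScenarioResult) -> pd.DataFrame:
    """Estimated current spending: the from-zero cube minus the incremental cube.

    Both runs must use the same configuration. Every cell of the difference
    is non-negative (scaling up from zero always costs at least as much as
    scaling up from a positive baseline).
    """
    if inc.mode is not ScenarioMode.incremental or fz.mode is not ScenarioMode.from_zero:
        raise ValidationError("expected (incremental, from_zero) scenario results")
    if inc.metadata["config_hash"] != fz.metadata["config_hash"]:
        raise ValidationError("scenario results come from different configurations")
    keys = ["country_id", "item_id", "item_kind", "year", "cost_category"]
    merged = fz.cube.merge(inc.cube, on=keys, how="outer", suffixes=("_fz", "_inc"))
    merged[["amount_fz", "amount_inc"]] = merged[["amount_fz", "amount_inc"]].fillna(0.0)
    diff = merged["amount_fz"] - merged["amount_inc"]
    if (diff < -1e-6 * max(1.0, float(merged["amount_fz"].abs().max()))).any():
        raise ValidationError("negative current-spending cell; configs inconsistent")
    out = merged[keys].copy()
    out["amount"] = diff.clip(lower=0.0)
    return out.sort_values(keys, kind="mergesort").reset_index(drop=True)


def annualized_total(cube: pd.DataFrame, years: int = 5) -> float:
    """Cube total divided by the number of model years (default 5)."""
    return cube_total(cube) / years


def _attach_keys(cube: pd.DataFrame, config: ModelConfig) -> pd.DataFrame:
    df = cube.copy()
    region = {c.country_id: c.who_region.value for c in config.countries}
    income = {c.country_id: c.income_group.value for c in config.countries}
    group = {s.intervention_id: s.group for s in config.interventions}
    df["who_region"] = df["country_id"].map(region)
    df["income_group"] = df["country_id"].map(income)
    df["intervention_group"] = df.apply(
        lambda r: group.get(r["item_id"], PROGRAMME_GROUP)
        if r["item_kind"] == "intervention" else PROGRAMME_GROUP,
        axis=1,
    )
    return df


def aggregate(cube: pd.DataFrame, by: list[str] | tuple[str, ...], config: ModelConfig) -> pd.DataFrame:
    """Sum the cube over a subset of reporting keys.

    Returns one row per group with ``amount`` (US$) and ``share_pct`` (the
    group's percentage of the grand total). Groups partition the grand
    total exactly, so shares sum to 100.
    """
    by = list(by)
    unknown = [k for k in by if k not in GROUPING_KEYS]
    if unknown:
        raise ValidationError(f"unknown grouping keys {unknown}; valid: {GROUPING_KEYS}")
    if not by:
        raise ValidationError("need at least one grouping key")
    df = _attach_keys(cube, config)
    out = df.groupby(by, as_index=False, sort=True)["amount"].sum()
    total = out["amount"].sum()
    out["share_pct"] = 100.0 * out["amount"] / total if total > 0 else 0.0
    return out


def per_head_metrics(cube: pd.DataFrame, config: ModelConfig) -> pd.DataFrame:
    """Per-adolescent and per-capita US$ by year.

    Populations are the registry 2010 stocks projected with each country's
    growth rate and summed over all countries in the configuration.
    """
    rows = []
    yearly = cube.groupby("year")["amount"].sum()
    for year in MODEL_YEARS:
        adol = sum(
            c.adol_pop_2010 * (1.0 + c.pop_growth_rate) ** (year - 2010)
            for c in config.countries
        )
        total_pop = sum(
            c.total_pop_2010 * (1.0 + c.pop_growth_rate) ** (year - 2010)
            for c in config.countries
        )
        if adol <= 0 or total_pop <= 0:
            raise ValidationError(f"non-positive population in {year}")
        amount = float(yearly.get(year, 0.0))
        rows.append({
            "year": year,
            "total_usd": amount,
            "per_adolescent_usd": amount / adol,
            "per_capita_usd": amount / total_pop,
        })
    return pd.DataFrame(rows)


def write_cube(cube: pd.DataFrame, path: str | Path) -> None:
    """Export a cube as tidy CSV (one row per cell, unformatted floats)."""
    cube.to_csv(path, index=False)
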