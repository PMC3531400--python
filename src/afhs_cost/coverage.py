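"""Coverage scale-up trajectories.

Coverage of each intervention in each country rises linearly from its 2010
baseline to the universal-access target (95%, or 50% for opioid
substitution therapy) in 2015. The quantity that is costed each year is the
*incremental* coverage above the baseline. Two scenario modes exist:
``incremental`` (scale up from observed baselines — the price tag) and
``from_zero`` (scale up from 0% — used to back out current spending by
subtraction).

The anchor convention: coverage equals the baseline at the anchor year
(2010 by default) and the target at 2015, so the first costed year, 2011,
already carries one fifth of the gap. The anchor is configurable because
the alternative (2011 at baseline) is equally defensible.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import ValidationError
from .registry import InterventionSpec


class ScenarioMode(str, Enum):
    incremental = "incremental"
    from_zero = "from_zero"


START_YEAR = 2011
END_YEAR = 2015
DEFAULT_ANCHOR_YEAR = 2010


@dataclass(frozen=True)
class CoverageTrajectory:
    country_id: str
    intervention_id: str
    baseline: float
    target: float
    mode: ScenarioMode = ScenarioMode.incremental
    start_year: int = START_YEAR
    end_year: int = END_YEAR
    anchor_year: int = DEFAULT_ANCHOR_YEAR

    def __post_init__(self) -> None:
        for name in ("baseline", "target"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} {v} outside [0, 1]")
        if self.mode is ScenarioMode.from_zero and self.baseline != 0.0:
            raise ValidationError("from_zero trajectories must have baseline 0")
        if not self.anchor_year < self.start_year <= self.end_year:
            raise ValidationError(
                f"need anchor {self.anchor_year} < start {self.start_year} "
                f"<= end {self.end_year}"
            )


def make_trajectory(
    country_id: str,
    spec: InterventionSpec,
    baseline: float,
    mode: ScenarioMode,
    anchor_year: int = DEFAULT_ANCHOR_YEAR,
) -> CoverageTrajectory:
    """Build a trajectory from a configured baseline, validating the range."""
    lo, hi = spec.coverage_range
    if not (lo - 1e-12 <= baseline <= hi + 1e-12):
        raise ValidationError(
            f"baseline {baseline} for {country_id}/{spec.intervention_id} "
            f"outside catalogue coverage range [{lo}, {hi}]"
        )
    return CoverageTrajectory(
        country_id=country_id,
        intervention_id=spec.intervention_id,
        baseline=0.0 if mode is ScenarioMode.from_zero else baseline,
        target=spec.target_coverage,
        mode=mode,
        anchor_year=anchor_year,
    )


def coverage_at(traj: CoverageTrajectory, year: int) -> float:
    """Linearly interpolated coverage in ``year``.

    Returns the target exactly at the end year (no floating drift).
    """
    if not (traj.start_year <= year <= traj.end_year):
        raise ValidationError(
            f"year {year} outside costing window [{traj.start_year}, {traj.end_year}]"
        )
    if year == traj.end_year:
        return traj.target
    frac = (year - traj.anchor_year) / (traj.end_year - traj.anchor_year)
    return traj.baseline + frac * (traj.target - traj.baseline)


def incremental_coverage(traj: CoverageTrajectory, year: int) -> float:
    """Coverage gained above the baseline by ``year``, clamped at zero.

    In ``from_zero`` mode the baseline is zero, so the whole trajectory is
    incremental. A baseline already above the target (e.g. childbirth care
    reported at 98.8%) yields zero increment in every year: dis-investment
    is out of scope.
    """
    if traj.target <= traj.baseline:
        # interpolation would run downhill; nothing to cost
        coverage_at(traj, year)  # still validate the year
        return 0.0
    return max(0.0, coverage_at(traj, year) - traj.baseline)
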