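"""Societal costing extension: productivity, informal care, out-of-pocket.

The NHS-perspective state costs are augmented with three nonnegative
increments:

* **productivity** - long-term absenteeism costed by the friction-cost
  approach (an employer's loss ends when the worker is replaced), charged
  once per treatment-line entry at the cohort's working-age employment
  rate; premature-mortality production losses are charged on inflow into
  the death states, by either the friction-cost or the human-capital
  method (lost earnings to retirement age), age-resolved per cycle;
* **informal care** - unpaid carer hours per cycle per state class at a
  unit cost per hour;
* **out-of-pocket** - patient-borne travel and miscellaneous expenses per
  cycle per state class.

Health outcomes are untouched: the societal perspective changes costs only.
A zero spec reproduces the NHS perspective exactly.  Nursing-home admission
costs are deliberately excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import (
    SOC_ONEOFF_LINE_ENTRY,
    SOC_PERCYCLE_BSC,
    SOC_PERCYCLE_REMISSION,
    SOC_PERCYCLE_TREATMENT,
)
from .params import ParameterError, ParameterSet

__all__ = [
    "SocietalCostSpec",
    "friction_productivity_cost",
    "apply_societal",
    "spec_from_params",
    "zero_spec",
    "mortality_loss_schedule",
]


@dataclass(frozen=True)
class SocietalCostSpec:
    """Unit costs and rates of the societal extension (GBP, 2013)."""

    daily_wage: float = 110.0
    #: (upper age bound, employment rate) bands, ascending
    employment_rate_by_age: tuple[tuple[float, float], ...] = (
        (55.0, 0.75), (65.0, 0.60), (float("inf"), 0.05),
    )
    friction_period_days: float = 90.0
    informal_care_hours_per_cycle: dict | None = None  # class -> hours
    informal_care_unit_cost: float = 15.0
    oop_cost_per_cycle: dict | None = None  # class -> GBP
    retirement_age_years: float = 65.0
    workdays_per_year: float = 248.0
    mortality_cost_approach: str = "friction"  # friction | human-capital

    def __post_init__(self):
        if self.mortality_cost_approach not in ("friction", "human-capital"):
            raise ParameterError(
                f"unknown mortality_cost_approach "
                f"{self.mortality_cost_approach!r}"
            )
        for v in (self.daily_wage, self.friction_period_days,
                  self.informal_care_unit_cost, self.workdays_per_year):
            if v < 0:
                raise ParameterError("societal costs and rates must be >= 0")
        for _, rate in self.employment_rate_by_age:
            if not (0.0 <= rate <= 1.0):
                raise ParameterError("employment rates must lie in [0, 1]")

    def employment_rate(self, age_years: float) -> float:
        for upper, rate in self.employment_rate_by_age:
            if age_years < upper:
                return rate
        return self.employment_rate_by_age[-1][1]

    @property
    def workday_fraction(self) -> float:
        """Workdays per calendar day (converts friction calendar days to
        paid days lost)."""
        return self.workdays_per_year / 365.25


def zero_spec() -> SocietalCostSpec:
    """A spec with every increment zero: the NHS perspective."""
    return SocietalCostSpec(
        daily_wage=0.0,
        employment_rate_by_age=((float("inf"), 0.0),),
        friction_period_days=0.0,
        informal_care_hours_per_cycle={},
        informal_care_unit_cost=0.0,
        oop_cost_per_cycle={},
    )


def spec_from_params(
    ps: ParameterSet, mortality_cost_approach: str = "friction"
) -> SocietalCostSpec:
    """Build the spec from the ``soc__*`` parameters of a set."""
    v = ps.value
    return SocietalCostSpec(
        daily_wage=v("soc__daily_wage"),
        employment_rate_by_age=(
            (55.0, v("soc__emp_16_54")),
            (65.0, v("soc__emp_55_64")),
            (float("inf"), v("soc__emp_65p")),
        ),
        friction_period_days=v("soc__friction_days"),
        informal_care_hours_per_cycle={
            "treatment": v("soc__ic_hours_treatment"),
            "remission": v("soc__ic_hours_remission"),
            "bsc": v("soc__ic_hours_bsc"),
        },
        informal_care_unit_cost=v("soc__ic_unit_cost"),
        oop_cost_per_cycle={
            "treatment": v("soc__oop_treatment"),
            "remission": v("soc__oop_remission"),
            "bsc": v("soc__oop_bsc"),
        },
        retirement_age_years=v("soc__retirement_age"),
        workdays_per_year=v("soc__workdays_per_year"),
        mortality_cost_approach=mortality_cost_approach,
    )


def friction_productivity_cost(
    absence_days: float, spec: SocietalCostSpec, age_years: float
) -> float:
    """Friction-cost value of a work absence: the daily wage times the
    employment rate at that age, for at most the friction period."""
    if absence_days < 0:
        raise ParameterError("absence_days must be >= 0")
    days = min(absence_days, spec.friction_period_days)
    return spec.daily_wage * spec.employment_rate(age_years) * days


def _ic(spec: SocietalCostSpec, cls: str) -> float:
    hours = (spec.informal_care_hours_per_cycle or {}).get(cls, 0.0)
    oop = (spec.oop_cost_per_cycle or {}).get(cls, 0.0)
    return hours * spec.informal_care_unit_cost + oop


def apply_societal(base: ParameterSet, spec: SocietalCostSpec) -> ParameterSet:
    """Parameter set whose state costs carry the societal increments.

    Per-cycle informal-care + out-of-pocket increments are resolved into the
    ``soc__percycle__*`` parameters every state references; the friction
    productivity cost of starting a treatment line (evaluated at the cohort
    starting age) into ``soc__oneoff__line_entry``; and the premature-
    mortality loss schedule is attached for age-resolved accrual at death.
    A zero spec returns costs identical to the NHS perspective.
    """
    age0 = base.starting_age_years
    line_entry = friction_productivity_cost(
        spec.friction_period_days, spec, age0
    ) * spec.workday_fraction
    out = base.resolve({
        SOC_PERCYCLE_TREATMENT: _ic(spec, "treatment"),
        SOC_PERCYCLE_REMISSION: _ic(spec, "remission"),
        SOC_PERCYCLE_BSC: _ic(spec, "bsc"),
        SOC_ONEOFF_LINE_ENTRY: line_entry,
    })
    import dataclasses

    return dataclasses.replace(out, societal=spec)


def mortality_loss_schedule(
    params: ParameterSet, spec: SocietalCostSpec, n_cycles: int
) -> np.ndarray:
    """Premature-mortality production loss per unit of death inflow at each
    cycle (zero at and beyond retirement age).

    ``friction``: one friction period of paid days at the age-specific
    employment rate.  ``human-capital``: paid days from the age at death to
    retirement.
    """
    ages = params.starting_age_years + np.arange(n_cycles) * params.cycle_years
    emp = np.array([spec.employment_rate(a) for a in ages])
    working = ages < spec.retirement_age_years
    if spec.mortality_cost_approach == "human-capital":
        years_lost = np.maximum(spec.retirement_age_years - ages, 0.0)
        days = years_lost * spec.workdays_per_year
    else:
        days = np.full(n_cycles, spec.friction_period_days * spec.workday_fraction)
    return np.where(working, spec.daily_wage * emp * days, 0.0)
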