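"""Human-capital valuation of on-farm fatalities.

Each death is valued as the sum of five components, all expressed in
base-year (2023) dollars:

``future_earnings``
    Present value of the earnings stream the decedent would have produced:
    occupation-matched annual earnings, scaled by an age-dependent FTE
    retirement trajectory (0.9 FTE to age 71, declining to 0.5 by 75, fully
    retired from 76), summed over the remaining life expectancy from the
    life table and discounted at the configured annual rate.

``household_production``
    Present value of unpaid household contributions, a flat annual value
    accruing from age 16 to a sex-specific end age (76 for men, 82 for
    women).

``friction``
    Employer disruption during the year of death, valued at a fraction
    (default 25%) of one annual salary.

``fixed_direct``
    Funeral, coronial, investigation and emergency-response components at
    configured fixed magnitudes.

``compensation``
    Lump-sum insurance payout, applied only when the death was
    work-related.

Nominal amounts are taken to be denominated in year-of-death dollars and
re-expressed in base-year dollars with the CPI series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import (
    ConfigurationError,
    CostParameters,
    CPISeries,
    EarningsSchedule,
    LifeTable,
    ParameterSet,
)
from .records import FatalityCase

COMPONENTS = (
    "future_earnings",
    "household_production",
    "friction",
    "fixed_direct",
    "compensation",
)


@dataclass(frozen=True)
class CostBreakdown:
    """Per-case valuation split into named components, base-year dollars."""

    components: dict[str, float]
    total: float
    base_year: int

    def __post_init__(self) -> None:
        if set(self.components) != set(COMPONENTS):
            raise ValueError(f"components must be exactly {COMPONENTS}")
        if any(v < 0 for v in self.components.values()):
            raise ValueError("cost components must be non-negative")
        s = sum(self.components.values())
        if abs(self.total - s) > 1e-6 * max(1.0, abs(s)):
            raise ValueError(f"total {self.total} != component sum {s}")


def fte_multiplier(age: float, params: CostParameters) -> float:
    """Fraction of a full working year worked at ``age``."""
    return params.fte_at(age)


def pv_future_earnings(
    case: FatalityCase,
    life_table: LifeTable,
    earnings: EarningsSchedule,
    params: CostParameters,
) -> float:
    """Present value of forgone earnings over the remaining life expectancy.

    The horizon is the rounded-up remaining life expectancy at the age of
    death; year ``t`` (1-based) contributes
    ``salary x FTE(age + t) / (1 + r)^t``.
    """
    salary = earnings.annual_earnings(case.occupation_code)
    horizon = math.ceil(life_table.remaining_years(case.age, case.sex))
    r = params.discount_rate
    pv = 0.0
    for t in range(1, horizon + 1):
        fte = params.fte_at(case.age + t)
        if fte:
            pv += salary * fte / (1.0 + r) ** t
    return pv


def pv_household_production(case: FatalityCase, params: CostParameters) -> float:
    """Present value of lost household production.

    Accrues for every future year in which the decedent would have been
    between ``hp_start_age`` and the sex-specific end age, inclusive.
    """
    end_age = params.hp_end_age(case.sex)
    r = params.discount_rate
    pv = 0.0
    for t in range(1, max(0, end_age - case.age) + 1):
        if case.age + t >= params.hp_start_age:
            pv += params.hp_annual_value / (1.0 + r) ** t
    return pv


def friction_cost(annual_salary: float, params: CostParameters) -> float:
    """Employer friction cost: a configured fraction of one annual salary."""
    if annual_salary < 0:
        raise ValueError(f"annual salary must be non-negative, got {annual_salary}")
    return annual_salary * params.friction_fraction


def index_to_base_year(amount: float, year: int, cpi: CPISeries) -> float:
    """Re-express ``amount`` (nominal, ``year`` dollars) in base-year dollars."""
    return amount * cpi.value(cpi.base_year) / cpi.value(year)


def case_cost(
    case: FatalityCase,
    life_table: LifeTable,
    earnings: EarningsSchedule,
    cpi: CPISeries,
    params: CostParameters,
) -> CostBreakdown:
    """Full valuation of one fatality in base-year dollars."""
    salary = earnings.annual_earnings(case.occupation_code)
    nominal = {
        "future_earnings": pv_future_earnings(case, life_table, earnings, params),
        "household_production": pv_household_production(case, params),
        "friction": friction_cost(salary, params),
        "fixed_direct": sum(params.fixed_costs.values()),
        "compensation": params.compensation_payout if case.work_related == "work" else 0.0,
    }
    components = {
        name: index_to_base_year(value, case.year, cpi)
        for name, value in nominal.items()
    }
    return CostBreakdown(
        components=components,
        total=sum(components.values()),
        base_year=cpi.base_year,
    )


def cost_cases(
    cases: list[FatalityCase], param_set: ParameterSet
) -> dict[str, CostBreakdown]:
    """Value a cohort; returns ``case_id -> CostBreakdown``."""
    return {
        case.case_id: case_cost(
            case, param_set.life_table, param_set.earnings, param_set.cpi, param_set.cost
        )
        for case in cases
    }


def annualise(total: float, n_years: int, rounding_multiple: float | None = None) -> float:
    """Average a period total over its years, optionally rounding for report."""
    if n_years <= 0:
        raise ValueError(f"n_years must be positive, got {n_years}")
    annual = total / n_years
    if rounding_multiple is not None:
        from .disclosure import round_to_multiple

        annual = round_to_multiple(annual, rounding_multiple)
    return annual


def adjust_for_coverage(
    annual_amount: float,
    params: CostParameters,
    rounding_multiple: float | None = None,
) -> float:
    """Scale an annual claims cost up for the uncovered share of the workforce.

    The published convention is multiplicative: ``amount x (1 + factor)``
    with factor 0.4.  For the alternative convention (divide by the covered
    fraction) set ``under_coverage_factor`` via
    :func:`coverage_factor_from_fraction`.
    """
    if annual_amount < 0:
        raise ValueError(f"annual amount must be non-negative, got {annual_amount}")
    if params.under_coverage_factor < 0:
        raise ConfigurationError("under_coverage_factor must be non-negative")
    scaled = annual_amount * (1.0 + params.under_coverage_factor)
    if rounding_multiple is not None:
        from .disclosure import round_to_multiple

        scaled = round_to_multiple(scaled, rounding_multiple)
    return scaled


def coverage_factor_from_fraction(coverage_fraction: float) -> float:
    """Uplift factor implied by dividing through the covered fraction.

    At 58% coverage this is 1/0.58 - 1 ~= 0.724, a stronger correction than
    the published 0.4 uplift; both conventions are supported.
    """
    if not 0.0 < coverage_fraction <= 1.0:
        raise ConfigurationError(
            f"coverage fraction must be in (0, 1], got {coverage_fraction}"
        )
    return 1.0 / coverage_fraction - 1.0
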