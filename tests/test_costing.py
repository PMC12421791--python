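"""Unit and property tests for the human-capital costing engine."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from farmburden import (
    CostParameters,
    CPISeries,
    EarningsSchedule,
    FatalityCase,
    LifeTable,
    ParameterSet,
    adjust_for_coverage,
    annualise,
    case_cost,
    coverage_factor_from_fraction,
    friction_cost,
    fte_multiplier,
    index_to_base_year,
    pv_future_earnings,
    pv_household_production,
)
from farmburden.params import ConfigurationError


def make_case(age, sex="male", work="work", year=2023, occ=None, case_id="X1"):
    return FatalityCase(
        case_id=case_id,
        year=year,
        age=age,
        sex=sex,
        work_related=work,
        agent_group="animal",
        agent="horse",
        occupation_code=occ,
    )


# --------------------------------------------------------------------------
# FTE retirement trajectory
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "age,expected",
    [
        (16, 0.9),
        (65, 0.9),
        (71, 0.9),
        (72, 0.8),
        (73, 0.7),
        (74, 0.6),
        (75, 0.5),
        (76, 0.0),
        (80, 0.0),
        (10, 0.0),  # below labour-force entry age
    ],
)
def test_fte_default_schedule(age, expected):
    assert fte_multiplier(age, CostParameters()) == pytest.approx(expected)


def test_fte_negative_age_rejected():
    with pytest.raises(ValueError):
        fte_multiplier(-1, CostParameters())


def test_fte_monotone_non_increasing_over_working_ages():
    p = CostParameters()
    values = [fte_multiplier(a, p) for a in range(16, 100)]
    assert all(a >= b for a, b in zip(values, values[1:]))


def test_fte_step_interpolation_variant():
    p = CostParameters(fte_interpolation="step")
    assert fte_multiplier(73, p) == 0.9  # holds the last anchor until the next
    assert fte_multiplier(75, p) == 0.5
    assert fte_multiplier(76, p) == 0.0


# --------------------------------------------------------------------------
# Present values
# --------------------------------------------------------------------------

def test_pv_earnings_zero_beyond_retirement(param_set):
    case = make_case(80)
    assert pv_future_earnings(case, param_set.life_table, param_set.earnings, param_set.cost) == 0.0


def test_pv_earnings_zero_discount_flat_fte_closed_form():
    """With r=0 and FTE pinned at 1.0, PV reduces exactly to salary x horizon."""
    horizon = 12
    lt = LifeTable(expectancy={"male": [float(horizon)] * 60})
    es = EarningsSchedule(earnings={"1": 1.0}, default_earnings=60_000.0)
    p = CostParameters(discount_rate=0.0, entry_age=0, fte_anchors=[(150, 1.0)])
    assert pv_future_earnings(make_case(30), lt, es, p) == pytest.approx(
        60_000.0 * horizon, rel=1e-12
    )


def test_pv_earnings_matches_bruteforce_oracle(param_set):
    """Year-by-year oracle with its own FTE table, age 40 at 3%."""
    case = make_case(40, occ="1211")
    salary = 85_000.0
    horizon = math.ceil(param_set.life_table.remaining_years(40, "male"))

    def oracle_fte(age):
        if age < 16 or age >= 76:
            return 0.0
        if age <= 71:
            return 0.9
        return {72: 0.8, 73: 0.7, 74: 0.6, 75: 0.5}[age]

    expected = sum(
        salary * oracle_fte(40 + t) / 1.03**t for t in range(1, horizon + 1)
    )
    got = pv_future_earnings(case, param_set.life_table, param_set.earnings, param_set.cost)
    assert got == pytest.approx(expected, rel=1e-12)


def test_pv_earnings_unmatched_occupation_without_default_errors(param_set):
    es = EarningsSchedule(earnings={"1211": 85_000.0}, default_earnings=None)
    with pytest.raises(ConfigurationError):
        pv_future_earnings(make_case(40, occ="9999"), param_set.life_table, es, param_set.cost)


def test_pv_earnings_non_increasing_in_age(param_set):
    values = [
        pv_future_earnings(make_case(a, occ="1211"), param_set.life_table,
                           param_set.earnings, param_set.cost)
        for a in range(16, 96)
    ]
    assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))


def test_household_production_window():
    p = CostParameters()
    assert pv_household_production(make_case(77, sex="male"), p) == 0.0
    assert pv_household_production(make_case(76, sex="male"), p) == 0.0
    p0 = CostParameters(discount_rate=0.0)
    assert pv_household_production(make_case(81, sex="female"), p0) == pytest.approx(
        p0.hp_annual_value
    )


def test_household_production_child_starts_at_16():
    """For a 10-year-old boy, contributions run over ages 16..76 only."""
    p = CostParameters()
    expected = sum(
        p.hp_annual_value / 1.03**t for t in range(1, 76 - 10 + 1) if 10 + t >= 16
    )
    assert pv_household_production(make_case(10, sex="male"), p) == pytest.approx(
        expected, rel=1e-12
    )


@pytest.mark.parametrize("salary,expected", [(80_000, 20_000), (0, 0), (61_000, 15_250)])
def test_friction_cost(salary, expected):
    assert friction_cost(salary, CostParameters()) == expected


def test_friction_negative_salary_rejected():
    with pytest.raises(ValueError):
        friction_cost(-1.0, CostParameters())


# --------------------------------------------------------------------------
# CPI indexation
# --------------------------------------------------------------------------

def test_index_to_base_year():
    cpi = CPISeries(index={2013: 100.0, 2023: 130.0}, base_year=2023)
    assert index_to_base_year(1_000.0, 2023, cpi) == 1_000.0
    assert index_to_base_year(1_000.0, 2013, cpi) == pytest.approx(1_300.0)
    back = CPISeries(index={2013: 100.0, 2023: 130.0}, base_year=2013)
    roundtrip = index_to_base_year(index_to_base_year(1_000.0, 2013, cpi), 2023, back)
    assert roundtrip == pytest.approx(1_000.0, rel=1e-9)


def test_index_missing_year_errors():
    cpi = CPISeries(index={2023: 130.0}, base_year=2023)
    with pytest.raises(ConfigurationError, match="2019"):
        index_to_base_year(1.0, 2019, cpi)


# --------------------------------------------------------------------------
# Full case valuation
# --------------------------------------------------------------------------

def test_case_cost_compensation_only_when_work_related(param_set):
    work = case_cost(make_case(40, work="work"), param_set.life_table,
                     param_set.earnings, param_set.cpi, param_set.cost)
    non_work = case_cost(make_case(40, work="non_work"), param_set.life_table,
                         param_set.earnings, param_set.cpi, param_set.cost)
    assert non_work.components["compensation"] == 0.0
    assert work.components["compensation"] > 0.0
    for name in ("future_earnings", "household_production", "friction", "fixed_direct"):
        assert work.components[name] == non_work.components[name]


def test_case_cost_all_parameters_zeroed(param_set):
    p = CostParameters(
        friction_fraction=0.0,
        hp_annual_value=0.0,
        fixed_costs={},
        compensation_payout=0.0,
        fte_anchors=[(0, 0.0)],
    )
    bd = case_cost(make_case(40), param_set.life_table, param_set.earnings, param_set.cpi, p)
    assert bd.total == 0.0


def test_case_cost_oracle_equivalence_random_cases(param_set, cases_200):
    """Every breakdown equals an independent straight-loop recomputation."""
    lt, es, cpi, p = (
        param_set.life_table,
        param_set.earnings,
        param_set.cpi,
        param_set.cost,
    )
    for case in cases_200:
        bd = case_cost(case, lt, es, cpi, p)
        salary = es.annual_earnings(case.occupation_code)
        horizon = math.ceil(lt.remaining_years(case.age, case.sex))
        pv_e = sum(
            salary * p.fte_at(case.age + t) / (1 + p.discount_rate) ** t
            for t in range(1, horizon + 1)
        )
        end = 76 if case.sex == "male" else 82
        pv_h = sum(
            p.hp_annual_value / (1 + p.discount_rate) ** t
            for t in range(1, max(0, end - case.age) + 1)
            if case.age + t >= 16
        )
        nominal = (
            pv_e
            + pv_h
            + salary * p.friction_fraction
            + sum(p.fixed_costs.values())
            + (p.compensation_payout if case.work_related == "work" else 0.0)
        )
        expected = nominal * cpi.value(cpi.base_year) / cpi.value(case.year)
        assert bd.total == pytest.approx(expected, rel=1e-9)
        assert bd.total == pytest.approx(sum(bd.components.values()), rel=1e-9)
        assert all(v >= 0 for v in bd.components.values())


def test_doubling_hp_value_doubles_only_that_component(param_set):
    base = CostParameters()
    doubled = CostParameters(hp_annual_value=2 * base.hp_annual_value)
    case = make_case(40)
    bd1 = case_cost(case, param_set.life_table, param_set.earnings, param_set.cpi, base)
    bd2 = case_cost(case, param_set.life_table, param_set.earnings, param_set.cpi, doubled)
    assert bd2.components["household_production"] == pytest.approx(
        2 * bd1.components["household_production"], rel=1e-12
    )
    for name in ("future_earnings", "friction", "fixed_direct", "compensation"):
        assert bd2.components[name] == bd1.components[name]


# --------------------------------------------------------------------------
# Annualisation and coverage scaling
# --------------------------------------------------------------------------

def test_annualise():
    assert annualise(1.8e9, 11, rounding_multiple=1e6) == 164e6
    assert annualise(1.24e9, 11, rounding_multiple=1e6) == 113e6
    assert annualise(0.0, 3) == 0.0
    with pytest.raises(ValueError):
        annualise(1.0, 0)


def test_adjust_for_coverage():
    p = CostParameters()
    assert adjust_for_coverage(190, p, rounding_multiple=5) == 265
    identity = CostParameters(under_coverage_factor=0.0)
    assert adjust_for_coverage(123.4, identity) == 123.4
    # alternative convention: divide by the covered fraction
    alt = coverage_factor_from_fraction(0.58)
    assert alt == pytest.approx(0.7241, abs=1e-4)
    assert 190 * (1 + alt) == pytest.approx(327.6, abs=0.05)
    with pytest.raises(ValueError):
        adjust_for_coverage(-1.0, p)


@settings(derandomize=True, max_examples=50)
@given(
    hp=st.floats(0.0, 1e5),
    rate=st.floats(0.0, 0.1),
    age=st.integers(0, 100),
)
def test_household_production_scales_linearly(hp, rate, age):
    case = make_case(age, sex="female")
    p1 = CostParameters(hp_annual_value=hp, discount_rate=rate)
    p2 = CostParameters(hp_annual_value=3 * hp, discount_rate=rate)
    assert pv_household_production(case, p2) == pytest.approx(
        3 * pv_household_production(case, p1), rel=1e-9, abs=1e-9
    )
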