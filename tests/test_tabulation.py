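"""Tests for the summary-table builders."""

import collections
import math

import numpy as np
import pandas as pd
import pytest

from farmburden import (
    ClaimRecord,
    FatalityCase,
    age_band_cost_summary,
    claims_agency_summary,
    claims_period_summary,
    claims_time_cost_by_year,
    cost_cases,
    crosstab_fatalities,
    generate_claims,
    generate_fatality_cases,
    percent_share,
    serious_claim_medians,
)
from farmburden import published
from farmburden.disclosure import round_to_multiple
from farmburden.tabulate import render_money_table


def make_claim(claim_id="C1", fin_year="2013-14", weeks=6.0, cost=12_000.0,
               agency="animal_human_biological"):
    severity = "serious" if weeks >= 5 / 7 else "minor"
    return ClaimRecord(
        claim_id=claim_id,
        fin_year=fin_year,
        severity=severity,
        agency_group=agency,
        nature="fractures",
        mechanism="body_stressing",
        bodily_location="trunk",
        weeks_lost=weeks,
        cost=cost,
    )


# --------------------------------------------------------------------------
# percent_share
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "part,whole,expected",
    [(544, 748, 73), (513, 544, 94), (389, 748, 52), (0, 748, 0), (1, 200, 1)],
)
def test_percent_share(part, whole, expected):
    assert percent_share(part, whole) == expected


def test_percent_share_half_up_and_errors():
    assert percent_share(1, 8, ) == 13  # 12.5 rounds up
    with pytest.raises(ValueError):
        percent_share(1, 0)
    with pytest.raises(ValueError):
        percent_share(5, 4)


# --------------------------------------------------------------------------
# Fatality cross-tab
# --------------------------------------------------------------------------

def _cases_from_published_totals():
    """One case per published agent-total count; work status split
    arbitrarily (the grand total is the invariant under test)."""
    cases = []
    k = 0
    for group, agents in published.FATALITY_AGENT_TABLE.items():
        for agent, (_, _, total) in agents.items():
            for _ in range(total):
                k += 1
                cases.append(
                    FatalityCase(
                        case_id=f"F{k}",
                        year=2015,
                        age=50,
                        sex="male",
                        work_related="unknown" if group == "unknown" else
                        ("work" if k % 4 else "non_work"),
                        agent_group=group,
                        agent=agent,
                    )
                )
    return cases


def test_crosstab_grand_total_matches_cohort():
    mt = crosstab_fatalities(_cases_from_published_totals())
    assert mt.grand_total == 748


def test_crosstab_empty_input_all_zero():
    mt = crosstab_fatalities([])
    assert mt.grand_total == 0
    assert (mt.true == 0).all()
    assert (mt.mask == None).all()  # noqa: E711  zeros stay visible


def test_crosstab_top6_share_on_synthetic():
    cases = generate_fatality_cases(20_000, seed=13)
    mt = crosstab_fatalities(cases, mask=False)
    totals = dict(zip(mt.row_labels, mt.row_totals))
    top6 = sum(
        totals[k]
        for k in (
            "mobile_machinery/tractor", "farm_vehicles/quad", "farm_vehicles/utility",
            "farm_vehicles/ssv", "animal/horse", "farm_vehicles/motorbike",
        )
    )
    assert abs(top6 / 20_000 - 0.52) < 0.02


def test_crosstab_oracle_recount(cases_200):
    mt = crosstab_fatalities(cases_200, mask=False)
    tally = collections.Counter(
        (f"{c.agent_group}/{c.agent}", c.work_related) for c in cases_200
    )
    for i, row in enumerate(mt.row_labels):
        for j, col in enumerate(mt.col_labels):
            assert mt.true[i, j] == tally[(row, col)]


# --------------------------------------------------------------------------
# Age-band cost summary
# --------------------------------------------------------------------------

def test_age_band_summary_single_case(param_set):
    case = FatalityCase("F1", 2020, 40, "male", "work", "animal", "horse", "1211")
    breakdowns = cost_cases([case], param_set)
    frame = age_band_cost_summary([case], breakdowns)
    row = frame[frame.age_band == "35-44"].iloc[0]
    total = breakdowns["F1"].total
    assert row.n == 1 and row.total == pytest.approx(total)
    assert row.average == pytest.approx(total)
    empty = frame[frame.age_band == "<15"].iloc[0]
    assert empty.n == 0 and math.isnan(empty.average)


def test_age_band_render_divide_and_round():
    """The published (n, total) pairs reproduce all printed averages after
    nearest-$5,000 rounding, including the worked 87-case example."""
    frame = pd.DataFrame(
        [
            {"age_band": band, "n": n, "total": float(total), "average": total / n}
            for band, (n, total, _) in published.AGE_BAND_COSTS.items()
        ]
    )
    rendered = render_money_table(frame, ("average",), multiple=5_000)
    expected = [str(avg) for (_, _, avg) in published.AGE_BAND_COSTS.values()]
    assert rendered["average"].tolist() == expected
    assert rendered["average"].iloc[0] == "1985000"  # 172,540,000 over 87 cases


def test_empty_band_average_rendered_absent():
    frame = pd.DataFrame([{"age_band": "<15", "n": 0, "total": 0.0, "average": np.nan}])
    rendered = render_money_table(frame, ("average",))
    assert rendered["average"].iloc[0] == ""


# --------------------------------------------------------------------------
# Claims summaries
# --------------------------------------------------------------------------

def test_period_summary_counts_and_exclusion(claims_1k):
    frame = claims_period_summary(claims_1k)
    tally = collections.Counter((c.severity, c.fin_year) for c in claims_1k)
    p1 = ["2013-14", "2014-15", "2015-16", "2016-17"]
    for severity in ("minor", "serious"):
        expected = sum(tally[(severity, fy)] for fy in p1)
        row = frame[frame.severity == severity].iloc[0]
        assert row["total 2013-14 to 2016-17"] == expected
        assert row["annual_mean 2013-14 to 2016-17"] == pytest.approx(expected / 4)
    assert frame.attrs["excluded"] == 0


def test_period_summary_excludes_out_of_period_claims():
    claims = [make_claim("C1"), make_claim("C2", fin_year="2025-26")]
    frame = claims_period_summary(claims)
    assert frame.attrs["excluded"] == 1
    assert frame[frame.severity == "Total"]["total 2013-14 to 2016-17"].iloc[0] == 1


def test_one_claim_annual_mean_rounds_to_zero():
    frame = claims_period_summary([make_claim()])
    mean = frame[frame.severity == "Total"]["annual_mean 2013-14 to 2016-17"].iloc[0]
    assert round_to_multiple(mean, 5) == 0


def test_agency_summary_single_group_is_100pct():
    frame = claims_agency_summary([make_claim(), make_claim("C2", weeks=0.1, cost=50.0)])
    row = frame[frame.agency_group == "animal_human_biological"].iloc[0]
    assert row["percent 2013-14 to 2016-17"] == 100


def test_agency_summary_percent_columns_sum_to_100(claims_1k):
    frame = claims_agency_summary(claims_1k)
    body = frame[frame.agency_group != "Total"]
    for col in ("percent 2013-14 to 2016-17", "percent 2017-18 to 2021-22"):
        assert 99 <= body[col].sum() <= 101


def test_agency_summary_unknown_group_rejected():
    bad = ClaimRecord("C9", "2013-14", "serious", "volcanic", "fractures",
                      "body_stressing", "trunk", 6.0, 1.0)
    with pytest.raises(ValueError, match="volcanic"):
        claims_agency_summary([bad])


def test_agency_summary_oracle_recount(claims_1k):
    frame = claims_agency_summary(claims_1k)
    tally = collections.Counter(c.agency_group for c in claims_1k)
    body = frame[frame.agency_group != "Total"]
    col_totals = body[["total 2013-14 to 2016-17", "total 2017-18 to 2021-22"]].sum(axis=1)
    for g, t in zip(body.agency_group, col_totals):
        assert t == tally[g]


def test_time_cost_by_year_sums_and_percentages(claims_1k):
    frame = claims_time_cost_by_year(claims_1k)
    by_year_weeks = collections.defaultdict(float)
    by_year_cost = collections.defaultdict(float)
    for c in claims_1k:
        by_year_weeks[c.fin_year] += c.weeks_lost
        by_year_cost[c.fin_year] += c.cost
    grand = frame[frame.fin_year == "Total"].iloc[0]
    assert grand.weeks == pytest.approx(sum(by_year_weeks.values()), rel=1e-12)
    assert grand.cost == pytest.approx(sum(by_year_cost.values()), rel=1e-12)
    assert grand.weeks_pct == 100 and grand.cost_pct == 100
    subtotals = frame[frame.fin_year == "Sub Total"]
    assert subtotals.weeks.sum() == pytest.approx(grand.weeks, rel=1e-12)
    assert subtotals.cost.sum() == pytest.approx(grand.cost, rel=1e-12)
    row = frame[frame.fin_year == "2013-14"].iloc[0]
    assert row.weeks == pytest.approx(by_year_weeks["2013-14"], rel=1e-12)


def test_time_cost_single_year_carries_all():
    claims = [make_claim("C1", weeks=6.0, cost=100.0), make_claim("C2", weeks=8.0, cost=300.0)]
    frame = claims_time_cost_by_year(claims)
    row = frame[frame.fin_year == "2013-14"].iloc[0]
    assert row.weeks_pct == 100 and row.cost_pct == 100


def test_printed_weeks_additivity():
    """The published annual weeks totals sum exactly to the printed
    sub-period and grand totals."""
    weeks = [v[0] for v in published.CLAIMS_TIME_COST_BY_YEAR.values()]
    assert sum(weeks[:4]) == published.CLAIMS_WEEKS_SUBTOTALS[0]
    assert sum(weeks[4:]) == published.CLAIMS_WEEKS_SUBTOTALS[1]
    assert sum(weeks) == published.CLAIMS_WEEKS_TOTAL


# --------------------------------------------------------------------------
# Serious-claim medians
# --------------------------------------------------------------------------

def test_median_midpoint_convention():
    claims = [make_claim(f"C{i}", weeks=w, cost=100.0 * w) for i, w in enumerate([4, 6, 9])]
    frame = serious_claim_medians(claims)
    assert frame[frame.fin_year == "2013-14"].median_weeks.iloc[0] == 6.0
    even = claims + [make_claim("C9", weeks=8, cost=800.0)]
    frame = serious_claim_medians(even)
    assert frame[frame.fin_year == "2013-14"].median_weeks.iloc[0] == 7.0  # midpoint of 6, 8


def test_median_single_claim_and_absent_years():
    frame = serious_claim_medians([make_claim(weeks=6.0)])
    assert frame.fin_year.tolist() == ["2013-14", "Total"]
    assert frame.median_weeks.tolist() == [6.0, 6.0]


def test_pooled_median_is_claim_level(claims_1k):
    frame = serious_claim_medians(claims_1k)
    serious = [c.weeks_lost for c in claims_1k if c.severity == "serious"
               and c.fin_year in published.COST_FIN_YEARS]
    assert frame[frame.fin_year == "Total"].median_weeks.iloc[0] == pytest.approx(
        float(np.median(serious))
    )
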