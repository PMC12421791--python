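"""Replay of the arithmetic connecting the published summary values.

The cohort-level dollar totals depend on restricted case-level data and
unpublished parameter magnitudes, so they cannot be recomputed here.  What
*can* be recomputed exactly is every piece of arithmetic that links the
printed values to one another: the percentage shares, the divide-and-round
annual means and averages, the column sums, the annualisation of the
headline totals, and the coverage-scaled annual claims figure.  Each check
recomputes the quantity from the printed inputs with the package's own
rounding/percentage primitives and compares to the printed result.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import published
from .costing import adjust_for_coverage, annualise
from .disclosure import round_to_multiple
from .params import CostParameters
from .tabulate import percent_share


@dataclass(frozen=True)
class Check:
    name: str
    expected: object
    computed: object
    detail: str = ""

    @property
    def passed(self) -> bool:
        return self.expected == self.computed


@dataclass(frozen=True)
class VerifyReport:
    checks: list[Check]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def render(self) -> str:
        lines = []
        for c in self.checks:
            status = "PASS" if c.passed else "FAIL"
            lines.append(f"[{status}] {c.name}: expected {c.expected}, computed {c.computed}")
            if c.detail:
                lines.append(f"       {c.detail}")
        n_pass = sum(c.passed for c in self.checks)
        lines.append(f"{n_pass}/{len(self.checks)} checks passed")
        return "\n".join(lines)


def verify_paper_arithmetic(
    count_multiple: int = 5,
    money_multiple: int = 5_000,
    grand_multiple: int = 5_000_000,
) -> VerifyReport:
    """Run the twelve published-arithmetic checks.

    The multiples default to the publication's rounding conventions
    (counts and annual means to 5, monetary averages to 5,000, narrative
    grand totals to 5,000,000); changing them is expected to break the
    corresponding checks, which is how the conventions were inferred.
    """
    p = published
    checks: list[Check] = []

    # 1. share of fatalities that were work-related
    checks.append(
        Check(
            "work_related_share_pct",
            73,
            percent_share(p.N_WORK_RELATED, p.N_FATALITIES),
            f"{p.N_WORK_RELATED}/{p.N_FATALITIES}",
        )
    )
    # 2. male share of work-related fatalities
    checks.append(
        Check(
            "male_share_of_work_pct",
            94,
            percent_share(p.N_MALE_WORK_RELATED, p.N_WORK_RELATED),
            f"{p.N_MALE_WORK_RELATED}/{p.N_WORK_RELATED}",
        )
    )
    # 3. the six leading agents account for 52% of all fatal cases
    six = sum(p.LEADING_AGENT_COUNTS.values())
    checks.append(
        Check(
            "six_leading_agents_share_pct",
            52,
            percent_share(six, p.N_FATALITIES),
            f"sum of six leading agent counts = {six}",
        )
    )
    # 4. agent-table internal totals: group totals and work-status margins
    group_sum = sum(p.FATALITY_AGENT_GROUP_TOTALS.values())
    margins = p.N_NON_WORK + p.N_WORK_RELATED + p.N_UNKNOWN_WORK_STATUS
    checks.append(
        Check(
            "fatality_table_totals",
            (p.N_FATALITIES, p.N_FATALITIES),
            (group_sum, margins),
            "agent-group totals and work-status margins both sum to the cohort",
        )
    )
    # 5. age-band averages: total / n, rounded to $5,000, for all bands + overall
    expected_avgs = tuple(avg for _, _, avg in p.AGE_BAND_COSTS.values())
    expected_avgs += (p.AGE_BAND_TOTAL_ROW[2],)
    computed_avgs = tuple(
        round_to_multiple(total / n, money_multiple)
        for n, total, _ in p.AGE_BAND_COSTS.values()
    )
    computed_avgs += (
        round_to_multiple(p.AGE_BAND_TOTAL_ROW[1] / p.AGE_BAND_TOTAL_ROW[0], money_multiple),
    )
    checks.append(
        Check(
            "age_band_average_costs",
            expected_avgs,
            computed_avgs,
            "seven band averages plus the overall average",
        )
    )
    # 6. severity x period annual means: total / n_years, rounded to 5
    n_years = {"period_1": 4, "period_2": 5}
    expected_means = []
    computed_means = []
    for (severity, period), (total, mean) in p.CLAIMS_BY_SEVERITY.items():
        expected_means.append(mean)
        computed_means.append(round_to_multiple(annualise(total, n_years[period]), count_multiple))
    checks.append(
        Check(
            "claims_severity_annual_means",
            tuple(expected_means),
            tuple(computed_means),
            "minor/serious/total means for both periods",
        )
    )
    # 7. severity totals align with the printed period totals to within the
    #    rounding multiple (the printed figures are independently rounded)
    gap_1 = abs(
        p.CLAIMS_BY_SEVERITY[("minor", "period_1")][0]
        + p.CLAIMS_BY_SEVERITY[("serious", "period_1")][0]
        - p.CLAIMS_BY_SEVERITY[("total", "period_1")][0]
    )
    gap_2 = abs(
        p.CLAIMS_BY_SEVERITY[("minor", "period_2")][0]
        + p.CLAIMS_BY_SEVERITY[("serious", "period_2")][0]
        - p.CLAIMS_BY_SEVERITY[("total", "period_2")][0]
    )
    checks.append(
        Check(
            "claims_severity_total_alignment",
            (True, True),
            (gap_1 <= count_multiple, gap_2 <= count_multiple),
            f"gaps of {gap_1} and {gap_2} vs rounding multiple {count_multiple}",
        )
    )
    # 8. agency-table example row: environmental agencies, first period
    env = p.CLAIMS_BY_AGENCY["environmental_agencies"]
    period_1_total = p.CLAIMS_BY_SEVERITY[("total", "period_1")][0]
    checks.append(
        Check(
            "agency_environmental_share_and_mean",
            (15, 765),
            (
                percent_share(env[0], period_1_total),
                round_to_multiple(annualise(env[0], 4), count_multiple),
            ),
            f"{env[0]} of {period_1_total} claims over four years",
        )
    )
    # 9. agency percent columns sum to 100 within rounding slack
    pct_1 = sum(v[1] for v in p.CLAIMS_BY_AGENCY.values())
    pct_2 = sum(v[4] for v in p.CLAIMS_BY_AGENCY.values())
    checks.append(
        Check(
            "agency_percent_columns_sum",
            (True, True),
            (99 <= pct_1 <= 101, 99 <= pct_2 <= 101),
            f"column sums {pct_1}% and {pct_2}%",
        )
    )
    # 10. time/cost table sums: weeks grand total, first-period cost subtotal,
    #     and the cost grand total after nearest-$5M rounding
    weeks_sum = sum(v[0] for v in p.CLAIMS_TIME_COST_BY_YEAR.values())
    cost_first = sum(
        p.CLAIMS_TIME_COST_BY_YEAR[fy][2] for fy in p.FIN_YEARS_PERIOD_1
    )
    cost_sum = sum(v[2] for v in p.CLAIMS_TIME_COST_BY_YEAR.values())
    checks.append(
        Check(
            "time_cost_table_sums",
            (p.CLAIMS_WEEKS_TOTAL, p.CLAIMS_COST_SUBTOTALS[0], p.CLAIMS_COST_TOTAL),
            (weeks_sum, cost_first, round_to_multiple(cost_sum, grand_multiple)),
            "second-period printed cost subtotal exceeds its cell sum by 1,000 "
            "(unrounded 2019-20 entry) and is deliberately not asserted",
        )
    )
    # 11. annualised fatality costs: headline total and work-related total
    checks.append(
        Check(
            "annualised_fatality_costs_m",
            (164, 113),
            (
                round_to_multiple(annualise(p.HEADLINE_TOTAL_COST, p.FATALITY_YEARS) / 1e6, 1),
                round_to_multiple(
                    annualise(p.WORK_RELATED_FATALITY_COST, p.FATALITY_YEARS) / 1e6, 1
                ),
            ),
            "1.8e9/11 -> 164; 1.24e9/11 -> 112.7, i.e. 113 to the nearest million "
            "(the narrative's 'approximately $112 million' reflects a different "
            "rounding convention; both are reported)",
        )
    )
    # 12. coverage scaling and combined annual figures, nearest $5M
    params = CostParameters()
    scaled = adjust_for_coverage(p.ANNUAL_CLAIMS_COST_M, params, rounding_multiple=5)
    combined = round_to_multiple(p.ANNUAL_FATALITY_COST_M + p.ANNUAL_CLAIMS_COST_M, 5)
    combined_work = round_to_multiple(
        p.ANNUAL_WORK_FATALITY_COST_M + p.ANNUAL_CLAIMS_COST_M, 5
    )
    checks.append(
        Check(
            "coverage_scaled_and_combined_m",
            (p.SCALED_ANNUAL_CLAIMS_COST_M, p.COMBINED_ANNUAL_COST_M, p.COMBINED_WORK_ANNUAL_COST_M),
            (scaled, combined, combined_work),
            "190 x 1.4 -> 265; 164 + 190 -> 355; 112 + 190 -> 300 ($M/year)",
        )
    )
    return VerifyReport(checks)
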