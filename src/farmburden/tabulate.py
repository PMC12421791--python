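"""Summary tables for the fatality and claims registries.

Reproduces the publication's six summary structures: the agent-by-work-status
fatality cross-tab, the age-band cost summary, claims by severity and
reporting period, claims by agency of injury, annual weeks-lost/cost totals,
and serious-claim medians.  All aggregates are computed from unrounded
values; multiple-based rounding is applied once, at render, by the
disclosure layer or the render helpers here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from . import published
from .costing import CostBreakdown
from .disclosure import MaskedTable, apply_disclosure, round_to_multiple
from .records import ClaimRecord, FatalityCase


@dataclass(frozen=True)
class PeriodDefinition:
    """A reporting period: an ordered list of member financial years."""

    label: str
    fin_years: tuple[str, ...]

    @property
    def n_years(self) -> int:
        return len(self.fin_years)


DEFAULT_PERIODS = (
    PeriodDefinition("2013-14 to 2016-17", tuple(published.FIN_YEARS_PERIOD_1)),
    PeriodDefinition("2017-18 to 2021-22", tuple(published.FIN_YEARS_PERIOD_2)),
)


@dataclass(frozen=True)
class AgeBand:
    """A half-open-at-the-top age band; ``upper`` of ``None`` means open."""

    label: str
    lower: int
    upper: int | None  # inclusive

    def contains(self, age: int) -> bool:
        return age >= self.lower and (self.upper is None or age <= self.upper)


DEFAULT_AGE_BANDS = (
    AgeBand("<15", 0, 14),
    AgeBand("15-24", 15, 24),
    AgeBand("25-34", 25, 34),
    AgeBand("35-44", 35, 44),
    AgeBand("45-54", 45, 54),
    AgeBand("55-64", 55, 64),
    AgeBand(">=65", 65, None),
)


def percent_share(part: int, whole: int) -> int:
    """Integer percentage, rounded half-up, in exact arithmetic."""
    if whole <= 0:
        raise ValueError(f"whole must be positive, got {whole}")
    if part > whole:
        raise ValueError(f"part {part} exceeds whole {whole}")
    frac = Fraction(100 * part, whole) + Fraction(1, 2)
    return math.floor(frac)


# --------------------------------------------------------------------------
# Fatalities
# --------------------------------------------------------------------------

def crosstab_fatalities(
    cases: list[FatalityCase],
    mask: bool = True,
    audit: bool = False,
) -> MaskedTable:
    """Agent x work-status cross-tabulation of fatality cases.

    Rows are ``group/agent`` categories in the packaged category order;
    columns are non-work / work / unknown status.  Small-cell suppression
    and complementary masking are applied unless ``mask`` is false.
    """
    row_labels = [
        f"{group}/{agent}"
        for group, agents in published.FATALITY_AGENT_TABLE.items()
        for agent in agents
    ]
    cols = ["non_work", "work", "unknown"]
    counts = pd.DataFrame(0, index=row_labels, columns=cols, dtype=np.int64)
    for case in cases:
        counts.loc[f"{case.agent_group}/{case.agent}", case.work_related] += 1
    if not mask:
        return MaskedTable.from_counts(counts, name="fatalities_by_agent")
    return apply_disclosure(counts, audit=audit, name="fatalities_by_agent")


def agent_group_totals(cases: list[FatalityCase]) -> pd.Series:
    ser = pd.Series(
        0, index=list(published.FATALITY_AGENT_TABLE), dtype=np.int64, name="n"
    )
    for case in cases:
        ser[case.agent_group] += 1
    return ser


def age_band_cost_summary(
    cases: list[FatalityCase],
    breakdowns: dict[str, CostBreakdown],
    bands: tuple[AgeBand, ...] = DEFAULT_AGE_BANDS,
) -> pd.DataFrame:
    """Cases, total and average cost per age band (unrounded values).

    ``average`` is NaN (reported as absent) for empty bands, never zero.
    """
    rows = []
    for band in bands:
        members = [c for c in cases if band.contains(c.age)]
        total = float(sum(breakdowns[c.case_id].total for c in members))
        n = len(members)
        rows.append(
            {
                "age_band": band.label,
                "n": n,
                "total": total,
                "average": total / n if n else np.nan,
            }
        )
    n_all = len(cases)
    total_all = float(sum(breakdowns[c.case_id].total for c in cases))
    rows.append(
        {
            "age_band": "Total",
            "n": n_all,
            "total": total_all,
            "average": total_all / n_all if n_all else np.nan,
        }
    )
    return pd.DataFrame(rows)


def render_money_table(
    frame: pd.DataFrame, money_cols: tuple[str, ...], multiple: float = 5_000
) -> pd.DataFrame:
    """Round the monetary columns of a summary for publication."""
    out = frame.copy()
    for col in money_cols:
        out[col] = [
            "" if pd.isna(v) else str(round_to_multiple(v, multiple)) for v in out[col]
        ]
    return out


# --------------------------------------------------------------------------
# Claims
# --------------------------------------------------------------------------

def _period_of(fin_year: str, periods: tuple[PeriodDefinition, ...]) -> str | None:
    for p in periods:
        if fin_year in p.fin_years:
            return p.label
    return None


def claims_period_summary(
    claims: list[ClaimRecord],
    periods: tuple[PeriodDefinition, ...] = DEFAULT_PERIODS,
) -> pd.DataFrame:
    """Claim totals and unrounded annual means by severity and period.

    Claims outside every period are excluded; the count of exclusions is
    attached as ``frame.attrs["excluded"]``.
    """
    totals = {(s, p.label): 0 for s in ("minor", "serious") for p in periods}
    excluded = 0
    for claim in claims:
        period = _period_of(claim.fin_year, periods)
        if period is None:
            excluded += 1
            continue
        totals[(claim.severity, period)] += 1
    rows = []
    for severity in ("minor", "serious"):
        row: dict[str, object] = {"severity": severity}
        for p in periods:
            t = totals[(severity, p.label)]
            row[f"total {p.label}"] = t
            row[f"annual_mean {p.label}"] = t / p.n_years
        rows.append(row)
    total_row: dict[str, object] = {"severity": "Total"}
    for p in periods:
        t = sum(totals[(s, p.label)] for s in ("minor", "serious"))
        total_row[f"total {p.label}"] = t
        total_row[f"annual_mean {p.label}"] = t / p.n_years
    rows.append(total_row)
    frame = pd.DataFrame(rows)
    frame.attrs["excluded"] = excluded
    return frame


def claims_agency_summary(
    claims: list[ClaimRecord],
    periods: tuple[PeriodDefinition, ...] = DEFAULT_PERIODS,
) -> pd.DataFrame:
    """Totals, integer percent shares and annual means by agency group."""
    groups = list(published.AGENCY_GROUPS)
    counts = {(g, p.label): 0 for g in groups for p in periods}
    for claim in claims:
        period = _period_of(claim.fin_year, periods)
        if period is None:
            continue
        if claim.agency_group not in published.AGENCY_GROUPS:
            raise ValueError(f"unknown agency group {claim.agency_group!r}")
        counts[(claim.agency_group, period)] += 1
    period_totals = {
        p.label: sum(counts[(g, p.label)] for g in groups) for p in periods
    }
    rows = []
    for g in groups:
        row: dict[str, object] = {"agency_group": g}
        for p in periods:
            t = counts[(g, p.label)]
            whole = period_totals[p.label]
            row[f"total {p.label}"] = t
            row[f"percent {p.label}"] = percent_share(t, whole) if whole else 0
            row[f"annual_mean {p.label}"] = t / p.n_years
        rows.append(row)
    total_row: dict[str, object] = {"agency_group": "Total"}
    for p in periods:
        total_row[f"total {p.label}"] = period_totals[p.label]
        total_row[f"percent {p.label}"] = 100
        total_row[f"annual_mean {p.label}"] = period_totals[p.label] / p.n_years
    rows.append(total_row)
    return pd.DataFrame(rows)


def claims_time_cost_by_year(
    claims: list[ClaimRecord],
    fin_years: tuple[str, ...] = tuple(published.COST_FIN_YEARS),
    subperiod_split: str = "2017-18",
) -> pd.DataFrame:
    """Annual weeks-lost and cost totals with sub-period subtotals.

    Percentages (of the grand totals, weeks and cost separately) are
    integer shares of unrounded sums.  Only the configured financial years
    (by default the eight with cost data) are tabulated.
    """
    weeks = {fy: 0.0 for fy in fin_years}
    cost = {fy: 0.0 for fy in fin_years}
    for claim in claims:
        if claim.fin_year in weeks:
            weeks[claim.fin_year] += claim.weeks_lost
            cost[claim.fin_year] += claim.cost
    grand_weeks = sum(weeks.values())
    grand_cost = sum(cost.values())

    def pct(part: float, whole: float) -> int:
        return round_to_multiple(100.0 * part / whole, 1) if whole else 0

    split_idx = fin_years.index(subperiod_split)
    blocks = [fin_years[:split_idx], fin_years[split_idx:]]
    rows = []
    for block in blocks:
        for fy in block:
            rows.append(
                {
                    "fin_year": fy,
                    "weeks": weeks[fy],
                    "weeks_pct": pct(weeks[fy], grand_weeks),
                    "cost": cost[fy],
                    "cost_pct": pct(cost[fy], grand_cost),
                }
            )
        bw = sum(weeks[fy] for fy in block)
        bc = sum(cost[fy] for fy in block)
        rows.append(
            {
                "fin_year": "Sub Total",
                "weeks": bw,
                "weeks_pct": pct(bw, grand_weeks),
                "cost": bc,
                "cost_pct": pct(bc, grand_cost),
            }
        )
    rows.append(
        {
            "fin_year": "Total",
            "weeks": grand_weeks,
            "weeks_pct": 100 if grand_weeks else 0,
            "cost": grand_cost,
            "cost_pct": 100 if grand_cost else 0,
        }
    )
    return pd.DataFrame(rows)


def serious_claim_medians(
    claims: list[ClaimRecord],
    fin_years: tuple[str, ...] = tuple(published.COST_FIN_YEARS),
) -> pd.DataFrame:
    """Median weeks lost and cost of serious claims, per year and pooled.

    Years without serious claims are absent; the ``Total`` row is the
    median of the pooled claim-level values (midpoint convention for even
    counts, via :func:`numpy.median`).
    """
    serious = [c for c in claims if c.severity == "serious" and c.fin_year in fin_years]
    rows = []
    for fy in fin_years:
        members = [c for c in serious if c.fin_year == fy]
        if not members:
            continue
        rows.append(
            {
                "fin_year": fy,
                "median_weeks": float(np.median([c.weeks_lost for c in members])),
                "median_cost": float(np.median([c.cost for c in members])),
            }
        )
    if serious:
        rows.append(
            {
                "fin_year": "Total",
                "median_weeks": float(np.median([c.weeks_lost for c in serious])),
                "median_cost": float(np.median([c.cost for c in serious])),
            }
        )
    return pd.DataFrame(rows, columns=["fin_year", "median_weeks", "median_cost"])
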