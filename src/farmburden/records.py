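"""Case-level record types for the two emulated registries.

A :class:`FatalityCase` mirrors one coronial record of an unintentional
on-farm death; a :class:`ClaimRecord` mirrors one accepted workers'
compensation claim.  Both carry only the fields the downstream costing and
tabulation stages consume, with controlled vocabularies for the categorical
axes so that malformed registries fail loudly at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import published

WORK_STATUSES = ("work", "non_work", "unknown")
SEXES = ("male", "female")
SEVERITIES = ("minor", "serious")

#: agent_group -> tuple of valid agent category strings.
AGENT_VOCABULARY: dict[str, tuple[str, ...]] = {
    group: tuple(agents) for group, agents in published.FATALITY_AGENT_TABLE.items()
}
AGENT_GROUPS = tuple(AGENT_VOCABULARY)

AGENCY_GROUPS = tuple(published.AGENCY_GROUPS)

NATURE_CATEGORIES = (
    "traumatic_joint_muscle",
    "wounds_lacerations",
    "fractures",
    "musculoskeletal_disease",
    "other",
)
MECHANISM_CATEGORIES = (
    "hit_by_moving_object",
    "body_stressing",
    "falls_trips_slips",
    "vehicle_incident",
    "other",
)
BODILY_LOCATIONS = ("upper_limbs", "lower_limbs", "trunk", "head", "other")

#: A claim is "serious" when five or more days were lost.  Weeks lost are
#: stored as calendar-week equivalents, so the boundary sits at 5/7 weeks.
SERIOUS_WEEKS_THRESHOLD = 5.0 / 7.0


class RecordError(ValueError):
    """A record violates one of its type invariants."""


@dataclass(frozen=True)
class FatalityCase:
    """One coronial record of an unintentional on-farm death."""

    case_id: str
    year: int
    age: int
    sex: str
    work_related: str
    agent_group: str
    agent: str
    occupation_code: str | None = None

    def validate(self, year_range: tuple[int, int] = published.FATALITY_YEAR_RANGE) -> None:
        if self.age < 0:
            raise RecordError(f"case {self.case_id}: age {self.age} is negative")
        if not year_range[0] <= self.year <= year_range[1]:
            raise RecordError(
                f"case {self.case_id}: year {self.year} outside {year_range[0]}-{year_range[1]}"
            )
        if self.sex not in SEXES:
            raise RecordError(f"case {self.case_id}: unknown sex {self.sex!r}")
        if self.work_related not in WORK_STATUSES:
            raise RecordError(
                f"case {self.case_id}: unknown work status {self.work_related!r}"
            )
        if self.agent_group not in AGENT_VOCABULARY:
            raise RecordError(
                f"case {self.case_id}: unknown agent group {self.agent_group!r}"
            )
        if self.agent not in AGENT_VOCABULARY[self.agent_group]:
            raise RecordError(
                f"case {self.case_id}: agent {self.agent!r} is not valid for "
                f"group {self.agent_group!r}"
            )


@dataclass(frozen=True)
class ClaimRecord:
    """One accepted workers' compensation claim."""

    claim_id: str
    fin_year: str
    severity: str
    agency_group: str
    nature: str
    mechanism: str
    bodily_location: str
    weeks_lost: float
    cost: float

    def validate(self, fin_years: tuple[str, ...] | None = None) -> None:
        if self.severity not in SEVERITIES:
            raise RecordError(f"claim {self.claim_id}: unknown severity {self.severity!r}")
        if self.agency_group not in AGENCY_GROUPS:
            raise RecordError(
                f"claim {self.claim_id}: unknown agency_group {self.agency_group!r}"
            )
        if self.nature not in NATURE_CATEGORIES:
            raise RecordError(f"claim {self.claim_id}: unknown nature {self.nature!r}")
        if self.mechanism not in MECHANISM_CATEGORIES:
            raise RecordError(
                f"claim {self.claim_id}: unknown mechanism {self.mechanism!r}"
            )
        if self.bodily_location not in BODILY_LOCATIONS:
            raise RecordError(
                f"claim {self.claim_id}: unknown bodily_location {self.bodily_location!r}"
            )
        if self.weeks_lost < 0:
            raise RecordError(
                f"claim {self.claim_id}: weeks_lost {self.weeks_lost} is negative"
            )
        if self.cost < 0:
            raise RecordError(f"claim {self.claim_id}: cost {self.cost} is negative")
        if fin_years is not None and self.fin_year not in fin_years:
            raise RecordError(
                f"claim {self.claim_id}: fin_year {self.fin_year!r} not in {fin_years}"
            )
        is_serious = self.weeks_lost >= SERIOUS_WEEKS_THRESHOLD
        if is_serious != (self.severity == "serious"):
            raise RecordError(
                f"claim {self.claim_id}: severity {self.severity!r} inconsistent with "
                f"{self.weeks_lost} weeks lost (serious threshold {SERIOUS_WEEKS_THRESHOLD:.4f})"
            )
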