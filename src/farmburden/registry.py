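"""Delimited-text persistence for the fatality and claims registries.

Both registries are UTF-8 CSV with a fixed header row.  Reading validates
every record against its type invariants and fails with the 1-based file
line number and the offending value; writing is deterministic, so the same
records always produce byte-identical files.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .records import ClaimRecord, FatalityCase, RecordError

FATALITY_COLUMNS = (
    "case_id",
    "year",
    "age",
    "sex",
    "work_related",
    "agent_group",
    "agent",
    "occupation_code",
)
CLAIM_COLUMNS = (
    "claim_id",
    "fin_year",
    "severity",
    "agency_group",
    "nature",
    "mechanism",
    "bodily_location",
    "weeks_lost",
    "cost",
)


class RegistryParseError(ValueError):
    """A registry file row could not be parsed or violates an invariant."""


def write_registry(records: list[FatalityCase] | list[ClaimRecord], path: str | Path) -> None:
    """Write a homogeneous record collection as CSV (schema from the type)."""
    if not records:
        raise ValueError("cannot infer registry schema from an empty collection")
    first = records[0]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        if isinstance(first, FatalityCase):
            writer.writerow(FATALITY_COLUMNS)
            for rec in records:
                rec.validate()
                writer.writerow(
                    [
                        rec.case_id,
                        rec.year,
                        rec.age,
                        rec.sex,
                        rec.work_related,
                        rec.agent_group,
                        rec.agent,
                        rec.occupation_code or "",
                    ]
                )
        elif isinstance(first, ClaimRecord):
            writer.writerow(CLAIM_COLUMNS)
            for rec in records:
                rec.validate()
                writer.writerow(
                    [
                        rec.claim_id,
                        rec.fin_year,
                        rec.severity,
                        rec.agency_group,
                        rec.nature,
                        rec.mechanism,
                        rec.bodily_location,
                        repr(float(rec.weeks_lost)),
                        repr(float(rec.cost)),
                    ]
                )
        else:
            raise TypeError(f"unsupported record type {type(first).__name__}")


def read_registry(path: str | Path) -> list[FatalityCase] | list[ClaimRecord]:
    """Read a registry CSV, dispatching on its header row.

    Raises :class:`RegistryParseError` naming the file line number on any
    malformed row or invariant violation.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = tuple(next(reader))
        except StopIteration:
            raise RegistryParseError(f"{path}: empty file") from None
        if header == FATALITY_COLUMNS:
            return _read_rows(reader, path, _parse_fatality)
        if header == CLAIM_COLUMNS:
            return _read_rows(reader, path, _parse_claim)
        raise RegistryParseError(f"{path}: unrecognised header {header}")


def _read_rows(reader, path, parse):
    records = []
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        try:
            rec = parse(row)
            rec.validate()
        except (RecordError, ValueError, IndexError) as exc:
            raise RegistryParseError(f"{path}: line {lineno}: {exc}") from None
        records.append(rec)
    return records


def _parse_fatality(row: list[str]) -> FatalityCase:
    if len(row) != len(FATALITY_COLUMNS):
        raise ValueError(f"expected {len(FATALITY_COLUMNS)} fields, got {len(row)}")
    return FatalityCase(
        case_id=row[0],
        year=int(row[1]),
        age=int(row[2]),
        sex=row[3],
        work_related=row[4],
        agent_group=row[5],
        agent=row[6],
        occupation_code=row[7] or None,
    )


def _parse_claim(row: list[str]) -> ClaimRecord:
    if len(row) != len(CLAIM_COLUMNS):
        raise ValueError(f"expected {len(CLAIM_COLUMNS)} fields, got {len(row)}")
    return ClaimRecord(
        claim_id=row[0],
        fin_year=row[1],
        severity=row[2],
        agency_group=row[3],
        nature=row[4],
        mechanism=row[5],
        bodily_location=row[6],
        weeks_lost=float(row[7]),
        cost=float(row[8]),
    )
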