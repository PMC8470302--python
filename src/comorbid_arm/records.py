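"""Discharge records and their CSV serialization.

One :class:`DischargeRecord` is one hospital discharge: demographic
strata, a principal diagnosis in F30-F39, and up to 20 additional
diagnoses.  The CSV layout is one row per discharge with the additional
codes semicolon-joined in a single column, so a cohort round-trips
losslessly through plain text.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .icd import mood_subgroup, normalize_code

__all__ = ["DischargeRecord", "RecordParseError", "read_records", "write_records", "CSV_HEADER"]

MAX_ADDITIONAL = 20

CSV_HEADER = [
    "record_id",
    "sex",
    "age_group",
    "insurance",
    "admission_route",
    "outcome",
    "bed_tier",
    "principal",
    "additional",
]

AGE_GROUPS = ("19-44", "45-64", "65-74", ">=75")
SEXES = ("male", "female")
INSURANCE_TYPES = ("national_health", "medicaid_1", "medicaid_2", "others")
ADMISSION_ROUTES = ("emergency", "outpatient", "others")
OUTCOMES = ("improved", "not_improved", "death", "others")
BED_TIERS = ("100-299", "300-499", "500-999", ">=1000")


class RecordParseError(ValueError):
    """Malformed row in a records CSV (reports the 1-based line number)."""


@dataclass(frozen=True)
class DischargeRecord:
    record_id: str
    sex: str
    age_group: str
    insurance: str
    admission_route: str
    outcome: str
    bed_tier: str
    principal: str
    additional: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.additional) > MAX_ADDITIONAL:
            raise ValueError(
                f"record {self.record_id}: {len(self.additional)} additional "
                f"diagnoses exceeds the maximum of {MAX_ADDITIONAL}"
            )
        # Raises NotInCohortError / CodeError for out-of-cohort principals.
        mood_subgroup(normalize_code(self.principal))
        object.__setattr__(self, "additional", tuple(self.additional))

    def with_additional(self, codes: Sequence[str]) -> "DischargeRecord":
        return replace(self, additional=tuple(codes))


def write_records(records: Iterable[DischargeRecord], path) -> None:
    """Write a cohort to CSV (additional codes semicolon-joined)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for r in records:
            writer.writerow(
                [
                    r.record_id,
                    r.sex,
                    r.age_group,
                    r.insurance,
                    r.admission_route,
                    r.outcome,
                    r.bed_tier,
                    r.principal,
                    ";".join(r.additional),
                ]
            )


def read_records(path) -> list[DischargeRecord]:
    """Read a cohort CSV; malformed rows raise with their line number."""
    records: list[DischargeRecord] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise RecordParseError(f"{path}: empty file") from None
        if header != CSV_HEADER:
            raise RecordParseError(f"{path}: unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CSV_HEADER):
                raise RecordParseError(
                    f"{path}:{lineno}: expected {len(CSV_HEADER)} fields, got {len(row)}"
                )
            additional = tuple(c for c in row[8].split(";") if c)
            try:
                records.append(
                    DischargeRecord(
                        record_id=row[0],
                        sex=row[1],
                        age_group=row[2],
                        insurance=row[3],
                        admission_route=row[4],
                        outcome=row[5],
                        bed_tier=row[6],
                        principal=row[7],
                        additional=additional,
                    )
                )
            except ValueError as exc:
                raise RecordParseError(f"{path}:{lineno}: {exc}") from exc
    return records
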