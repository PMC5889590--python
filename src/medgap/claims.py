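"""Domain types and delimited-text I/O for claims, eligibility and self-report tables.

Input format is plain CSV with a fixed header and ISO 8601 dates.  Claims
extracts are dirty in practice, so parsing collects per-row errors into a
:class:`ValidationReport` instead of failing on the first bad row; a strict
mode aborts on any error.  Therapeutic indication is taken as a given column
(the caller owns the drug→class mapping), never inferred from drug names.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CLAIMS_COLUMNS = ["patient_id", "fill_date", "ingredient", "indication", "days_supply"]
ELIGIBILITY_COLUMNS = ["patient_id", "continuous_benefits", "dual_coverage"]
SELFREPORT_COLUMNS = ["patient_id", "source", "indication", "response_date", "missed_days"]


class Indication(str, enum.Enum):
    """Therapeutic indication class of a dispensed drug."""

    DIABETES_ORAL = "diabetes_oral"
    BLOOD_PRESSURE = "blood_pressure"
    CHOLESTEROL = "cholesterol"
    INSULIN = "insulin"
    OTHER = "other"


#: Indications for which a gap measure is computed.  Insulin is excluded
#: because claims carry no fixed days-supply for dose-titrated insulin.
ANALYZABLE_INDICATIONS = (
    Indication.DIABETES_ORAL,
    Indication.BLOOD_PRESSURE,
    Indication.CHOLESTEROL,
)


class Source(str, enum.Enum):
    """Mode through which a 7-day missed-pill recall was collected."""

    ATSM = "atsm"
    INTERVIEW = "interview"


@dataclass(frozen=True, order=True)
class DispensingRecord:
    """One pharmacy fill: who, when, what, and how many days of supply."""

    patient_id: str
    fill_date: date
    ingredient: str
    indication: Indication
    days_supply: int

    def __post_init__(self) -> None:
        if self.days_supply < 1:
            raise ValueError(f"days_supply must be >= 1, got {self.days_supply}")


@dataclass(frozen=True)
class PatientEligibility:
    """Benefit status of one patient over the 12-month lookback.

    ``continuous_benefits`` must hold throughout the observation window for
    claims capture to be complete; ``dual_coverage`` marks patients whose
    alternative pharmacy benefit makes claims capture incomplete.
    """

    patient_id: str
    continuous_benefits: bool
    dual_coverage: bool


@dataclass(frozen=True)
class SelfReportResponse:
    """One 7-day recall answer: days with a missed pill, 0–7."""

    patient_id: str
    source: Source
    indication: Indication
    response_date: date
    missed_days: int

    def __post_init__(self) -> None:
        if not 0 <= self.missed_days <= 7:
            raise ValueError(f"missed_days must be in [0, 7], got {self.missed_days}")
        if self.indication is Indication.INSULIN:
            raise ValueError("insulin self-reports are outside the analyzable set")


@dataclass(frozen=True)
class RowError:
    """A validation failure pinned to a 1-based data row of the input file."""

    row: int
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row}: {self.field}: {self.message}"


@dataclass
class ValidationReport:
    """Per-row errors and file-level warnings collected while parsing."""

    path: str
    errors: list[RowError] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def add(self, row: int, column: str, message: str) -> None:
        self.errors.append(RowError(row, column, message))

    def raise_if_errors(self) -> None:
        if self.errors:
            detail = "; ".join(str(e) for e in self.errors[:10])
            raise ValueError(f"{self.path}: {len(self.errors)} invalid row(s): {detail}")


class StrictParseError(ValueError):
    """Raised in strict mode when any row fails validation."""


_BOOL_VALUES = {
    "true": True,
    "false": False,
    "1": True,
    "0": False,
    "t": True,
    "f": False,
    "yes": True,
    "no": False,
}


def _parse_bool(text: str) -> bool:
    try:
        return _BOOL_VALUES[text.strip().lower()]
    except KeyError:
        raise ValueError(f"not a boolean: {text!r}") from None


def _parse_date(text: str) -> date:
    return date.fromisoformat(text.strip())


def _parse_int(text: str) -> int:
    return int(text.strip())


def _read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return frame


def _finish(
    records: list, report: ValidationReport, strict: bool, what: str
) -> tuple[list, ValidationReport]:
    if strict and report.errors:
        report_head = "; ".join(str(e) for e in report.errors[:10])
        raise StrictParseError(
            f"{report.path}: {len(report.errors)} invalid {what} row(s): {report_head}"
        )
    if not records and not report.errors:
        msg = f"{report.path}: no {what} rows found"
        report.warnings.append(msg)
        logger.warning(msg)
    return records, report


def read_dispensings(
    path: str | Path, strict: bool = False
) -> tuple[list[DispensingRecord], ValidationReport]:
    """Read a claims CSV into dispensing records.

    Rows violating invariants (unparseable date, days_supply < 1, unknown
    indication) are dropped and recorded in the report with their row number.
    Same-day duplicate fills are retained here; they are merged downstream by
    the window-selection step.
    """
    frame = _read_table(path, CLAIMS_COLUMNS)
    report = ValidationReport(str(path))
    records: list[DispensingRecord] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            fill_date = _parse_date(row.fill_date)
        except ValueError:
            report.add(idx, "fill_date", f"invalid date {row.fill_date!r}")
            continue
        try:
            indication = Indication(row.indication.strip())
        except ValueError:
            report.add(idx, "indication", f"unknown indication {row.indication!r}")
            continue
        try:
            days_supply = _parse_int(row.days_supply)
        except ValueError:
            report.add(idx, "days_supply", f"not an integer: {row.days_supply!r}")
            continue
        if days_supply < 1:
            report.add(idx, "days_supply", f"must be >= 1, got {days_supply}")
            continue
        records.append(
            DispensingRecord(
                patient_id=str(row.patient_id).strip(),
                fill_date=fill_date,
                ingredient=str(row.ingredient).strip(),
                indication=indication,
                days_supply=days_supply,
            )
        )
    return _finish(records, report, strict, "dispensing")


def read_eligibility(
    path: str | Path, strict: bool = False
) -> tuple[dict[str, PatientEligibility], ValidationReport]:
    """Read the eligibility CSV, one row per patient.

    Duplicate patient_id rows violate the one-row-per-patient invariant and
    are recorded as errors (first occurrence wins).
    """
    frame = _read_table(path, ELIGIBILITY_COLUMNS)
    report = ValidationReport(str(path))
    table: dict[str, PatientEligibility] = {}
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        pid = str(row.patient_id).strip()
        if pid in table:
            report.add(idx, "patient_id", f"duplicate patient {pid!r}")
            continue
        try:
            continuous = _parse_bool(row.continuous_benefits)
            dual = _parse_bool(row.dual_coverage)
        except ValueError as exc:
            report.add(idx, "continuous_benefits/dual_coverage", str(exc))
            continue
        table[pid] = PatientEligibility(pid, continuous_benefits=continuous, dual_coverage=dual)
    records, report = _finish(list(table.values()), report, strict, "eligibility")
    return {r.patient_id: r for r in records}, report


def read_selfreports(
    path: str | Path, strict: bool = False
) -> tuple[list[SelfReportResponse], ValidationReport]:
    """Read the self-report CSV; missed_days outside [0, 7] is rejected."""
    frame = _read_table(path, SELFREPORT_COLUMNS)
    report = ValidationReport(str(path))
    records: list[SelfReportResponse] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            source = Source(row.source.strip())
        except ValueError:
            report.add(idx, "source", f"unknown source {row.source!r}")
            continue
        try:
            indication = Indication(row.indication.strip())
        except ValueError:
            report.add(idx, "indication", f"unknown indication {row.indication!r}")
            continue
        if indication is Indication.INSULIN:
            report.add(idx, "indication", "insulin self-reports are excluded")
            continue
        try:
            response_date = _parse_date(row.response_date)
        except ValueError:
            report.add(idx, "response_date", f"invalid date {row.response_date!r}")
            continue
        try:
            missed = _parse_int(row.missed_days)
        except ValueError:
            report.add(idx, "missed_days", f"not an integer: {row.missed_days!r}")
            continue
        if not 0 <= missed <= 7:
            report.add(idx, "missed_days", f"must be in [0, 7], got {missed}")
            continue
        records.append(
            SelfReportResponse(
                patient_id=str(row.patient_id).strip(),
                source=source,
                indication=indication,
                response_date=response_date,
                missed_days=missed,
            )
        )
    return _finish(records, report, strict, "self-report")


def write_dispensings(records: Iterable[DispensingRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "fill_date": r.fill_date.isoformat(),
                "ingredient": r.ingredient,
                "indication": r.indication.value,
                "days_supply": r.days_supply,
            }
            for r in records
        ],
        columns=CLAIMS_COLUMNS,
    )
    frame.to_csv(path, index=False)


def write_eligibility(records: Iterable[PatientEligibility], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "continuous_benefits": str(r.continuous_benefits).lower(),
                "dual_coverage": str(r.dual_coverage).lower(),
            }
            for r in records
        ],
        columns=ELIGIBILITY_COLUMNS,
    )
    frame.to_csv(path, index=False)


def write_selfreports(records: Iterable[SelfReportResponse], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "source": r.source.value,
                "indication": r.indication.value,
                "response_date": r.response_date.isoformat(),
                "missed_days": r.missed_days,
            }
            for r in records
        ],
        columns=SELFREPORT_COLUMNS,
    )
    frame.to_csv(path, index=False)


# Removal reasons, in gate-precedence order.  A record removed for more than
# one reason is tallied under the earliest gate so tallies are reproducible.
REMOVAL_REASONS = ("dual_coverage", "no_continuous_benefits", "insulin")


def filter_cohort(
    records: Iterable[DispensingRecord],
    eligibility: dict[str, PatientEligibility],
) -> tuple[list[DispensingRecord], dict[str, int]]:
    """Restrict fills to analyzable patients and indications.

    Removes all insulin fills and all fills of patients with dual coverage
    (incomplete claims capture) or without continuous benefits.  Returns the
    retained records unaltered, plus a removed-record tally keyed by reason.
    A patient present in the claims but absent from the eligibility table is
    a fatal inconsistency.
    """
    kept: list[DispensingRecord] = []
    tally: dict[str, int] = {reason: 0 for reason in REMOVAL_REASONS}
    for record in records:
        elig = eligibility.get(record.patient_id)
        if elig is None:
            raise KeyError(f"patient {record.patient_id!r} missing from eligibility table")
        if elig.dual_coverage:
            tally["dual_coverage"] += 1
        elif not elig.continuous_benefits:
            tally["no_continuous_benefits"] += 1
        elif record.indication is Indication.INSULIN:
            tally["insulin"] += 1
        else:
            kept.append(record)
    return kept, tally
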