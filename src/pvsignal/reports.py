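"""Data model, readers/writers and cohort filters for individual case
safety reports (ICSRs).

Two on-disk dialects are supported:

``jsonl``
    one JSON object per line, field names identical to the model fields;
``flat_csv``
    one row per (drug, reaction) combination; rows sharing ``report_id``
    are re-nested into a single report on read.
"""
from __future__ import annotations

import csv
import datetime as dt
import enum
import json
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .dates import FuzzyDate
from .errors import FormatError, RecordValidationError

Dialect = Literal["jsonl", "flat_csv"]


class DrugRole(str, enum.Enum):
    suspected = "suspected"
    concomitant = "concomitant"


class Route(str, enum.Enum):
    intravitreal = "intravitreal"
    oral = "oral"
    intravenous = "intravenous"
    subcutaneous = "subcutaneous"
    topical = "topical"
    other = "other"
    unreported = "unreported"


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class ReporterType(str, enum.Enum):
    physician = "physician"
    pharmacist = "pharmacist"
    consumer = "consumer"
    other = "other"


class ReportType(str, enum.Enum):
    spontaneous = "spontaneous"
    study = "study"
    other = "other"


class Outcome(str, enum.Enum):
    recovered = "recovered"
    recovering = "recovering"
    not_recovered = "not_recovered"
    fatal = "fatal"
    unknown = "unknown"


class ChallengeResult(str, enum.Enum):
    positive = "positive"
    negative = "negative"
    not_done = "not_done"
    unknown = "unknown"


class DrugRecord(BaseModel):
    """One drug entry on a report, identified by generic name."""

    model_config = ConfigDict(frozen=True)

    drug_name: str = Field(min_length=1)
    role: DrugRole
    route: Route = Route.unreported
    indication: Optional[str] = None
    start_date: Optional[FuzzyDate] = None
    dose_documented: bool = False


class ReactionRecord(BaseModel):
    """One suspected reaction, coded at preferred-term level."""

    model_config = ConfigDict(frozen=True)

    pt_name: str = Field(min_length=1)
    onset_date: Optional[FuzzyDate] = None


class ICSR(BaseModel):
    """One individual case safety report."""

    model_config = ConfigDict(frozen=True)

    report_id: str = Field(min_length=1)
    report_date: dt.date
    age_years: Optional[float] = Field(default=None, ge=0, le=120)
    sex: Optional[Sex] = None
    country: Optional[str] = None
    reporter_type: Optional[ReporterType] = None
    report_type: Optional[ReportType] = None
    outcome: Optional[Outcome] = None
    comment_present: bool = False
    drugs: tuple[DrugRecord, ...] = Field(min_length=1)
    reactions: tuple[ReactionRecord, ...] = Field(min_length=1)
    dechallenge: Optional[ChallengeResult] = None
    rechallenge: Optional[ChallengeResult] = None

    @model_validator(mode="after")
    def _dates_not_after_report(self) -> "ICSR":
        for d in self.drugs:
            if d.start_date is not None and d.start_date.date > self.report_date:
                raise ValueError(
                    f"drug start_date {d.start_date} after report_date "
                    f"{self.report_date} (report {self.report_id})"
                )
        for r in self.reactions:
            if r.onset_date is not None and r.onset_date.date > self.report_date:
                raise ValueError(
                    f"reaction onset_date {r.onset_date} after report_date "
                    f"{self.report_date} (report {self.report_id})"
                )
        return self

    def suspected_drugs(self) -> tuple[DrugRecord, ...]:
        return tuple(d for d in self.drugs if d.role is DrugRole.suspected)


# ---------------------------------------------------------------------------
# collection-level validation

def validate_collection(reports: Sequence[ICSR]) -> None:
    """Enforce cross-record invariants (unique report_id)."""
    seen: set[str] = set()
    for r in reports:
        if r.report_id in seen:
            raise RecordValidationError(
                f"duplicate report_id {r.report_id!r} in collection",
                report_id=r.report_id,
            )
        seen.add(r.report_id)


# ---------------------------------------------------------------------------
# I/O

_CSV_COLUMNS = [
    "report_id", "report_date", "age_years", "sex", "country",
    "reporter_type", "report_type", "outcome", "comment_present",
    "dechallenge", "rechallenge",
    "drug_name", "drug_role", "drug_route", "drug_indication",
    "drug_start_date", "dose_documented", "pt_name", "onset_date",
]

_DEMOGRAPHIC_COLS = _CSV_COLUMNS[:11]


def read_reports(
    path: str | Path,
    dialect: Dialect = "jsonl",
    errors: list[tuple[int, str]] | None = None,
) -> list[ICSR]:
    """Read and validate a report collection.

    When ``errors`` is given, malformed records are skipped and collected
    there as ``(line_number, message)`` pairs; otherwise the first
    malformed record raises :class:`RecordValidationError` naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "jsonl":
        reports = _read_jsonl(path, errors)
    elif dialect == "flat_csv":
        reports = _read_flat_csv(path, errors)
    else:
        raise FormatError(f"unsupported dialect {dialect!r}")
    validate_collection(reports)
    return reports


def _read_jsonl(path: Path, errors: list[tuple[int, str]] | None) -> list[ICSR]:
    reports: list[ICSR] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            try:
                reports.append(ICSR.model_validate(obj))
            except ValidationError as exc:
                rid = obj.get("report_id", "<missing>") if isinstance(obj, dict) else "<missing>"
                msg = f"report {rid!r}: {exc.errors()[0]['msg']}"
                if errors is None:
                    raise RecordValidationError(
                        f"{path}:{lineno}: {msg}", report_id=str(rid)
                    ) from exc
                errors.append((lineno, msg))
    return reports


def _read_flat_csv(path: Path, errors: list[tuple[int, str]] | None) -> list[ICSR]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "report_id" not in reader.fieldnames:
            raise FormatError(f"{path}: not a flat_csv report file (missing header)")
        rows = [(lineno, row) for lineno, row in enumerate(reader, start=2)]

    # group rows by report_id preserving first-appearance order
    groups: dict[str, list[tuple[int, dict]]] = {}
    for lineno, row in rows:
        groups.setdefault(row["report_id"], []).append((lineno, row))

    def opt(v: str | None) -> str | None:
        return v if v not in (None, "", "NA") else None

    reports: list[ICSR] = []
    for rid, grp in groups.items():
        first_line, first = grp[0]
        # demographics must agree across rows of one report
        for lineno, row in grp[1:]:
            conflict = [c for c in _DEMOGRAPHIC_COLS if row.get(c) != first.get(c)]
            if conflict:
                raise RecordValidationError(
                    f"report {rid!r}: conflicting demographics across rows "
                    f"(line {lineno}, fields {conflict})",
                    report_id=rid,
                )
        drugs: list[dict] = []
        reactions: list[dict] = []
        for _, row in grp:
            drug = {
                "drug_name": row.get("drug_name"),
                "role": row.get("drug_role"),
                "route": opt(row.get("drug_route")) or "unreported",
                "indication": opt(row.get("drug_indication")),
                "start_date": opt(row.get("drug_start_date")),
                "dose_documented": _parse_bool(row.get("dose_documented")),
            }
            if drug not in drugs:
                drugs.append(drug)
            rx = {"pt_name": row.get("pt_name"),
                  "onset_date": opt(row.get("onset_date"))}
            if rx not in reactions:
                reactions.append(rx)
        obj = {
            "report_id": rid,
            "report_date": first.get("report_date"),
            "age_years": opt(first.get("age_years")),
            "sex": opt(first.get("sex")),
            "country": opt(first.get("country")),
            "reporter_type": opt(first.get("reporter_type")),
            "report_type": opt(first.get("report_type")),
            "outcome": opt(first.get("outcome")),
            "comment_present": _parse_bool(first.get("comment_present")),
            "dechallenge": opt(first.get("dechallenge")),
            "rechallenge": opt(first.get("rechallenge")),
            "drugs": drugs,
            "reactions": reactions,
        }
        try:
            reports.append(ICSR.model_validate(obj))
        except ValidationError as exc:
            msg = f"report {rid!r}: {exc.errors()[0]['msg']}"
            if errors is None:
                raise RecordValidationError(
                    f"{path}:{first_line}: {msg}", report_id=rid
                ) from exc
            errors.append((first_line, msg))
    return reports


def _parse_bool(v: object) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in ("true", "1", "yes")


def write_reports(
    reports: Sequence[ICSR], path: str | Path, dialect: Dialect = "jsonl"
) -> None:
    """Write a validated collection; ``read_reports`` round-trips it."""
    validate_collection(reports)
    path = Path(path)
    if dialect == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for r in reports:
                fh.write(r.model_dump_json(exclude_none=True) + "\n")
    elif dialect == "flat_csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
            writer.writeheader()
            for r in reports:
                base = {
                    "report_id": r.report_id,
                    "report_date": r.report_date.isoformat(),
                    "age_years": "" if r.age_years is None else _fmt_age(r.age_years),
                    "sex": _enum_str(r.sex),
                    "country": r.country or "",
                    "reporter_type": _enum_str(r.reporter_type),
                    "report_type": _enum_str(r.report_type),
                    "outcome": _enum_str(r.outcome),
                    "comment_present": str(r.comment_present).lower(),
                    "dechallenge": _enum_str(r.dechallenge),
                    "rechallenge": _enum_str(r.rechallenge),
                }
                # one row per (drug, reaction) combination
                for d in r.drugs:
                    for rx in r.reactions:
                        row = dict(base)
                        row.update({
                            "drug_name": d.drug_name,
                            "drug_role": d.role.value,
                            "drug_route": d.route.value,
                            "drug_indication": d.indication or "",
                            "drug_start_date": d.start_date.isoformat() if d.start_date else "",
                            "dose_documented": str(d.dose_documented).lower(),
                            "pt_name": rx.pt_name,
                            "onset_date": rx.onset_date.isoformat() if rx.onset_date else "",
                        })
                        writer.writerow(row)
    else:
        raise FormatError(f"unsupported dialect {dialect!r}")


def _fmt_age(age: float) -> str:
    return str(int(age)) if float(age).is_integer() else repr(age)


def _enum_str(v: enum.Enum | None) -> str:
    return "" if v is None else v.value


# ---------------------------------------------------------------------------
# cohort filters

def select_exposed(
    reports: Iterable[ICSR],
    drug_names: set[str] | frozenset[str],
    route: Route | str,
    require_suspected: bool = True,
) -> list[ICSR]:
    """Reports exposed to one of ``drug_names`` via the given route.

    Matching is case-insensitive on generic name. A report whose only
    matching drug record has route ``unreported`` is excluded — an
    unreported route cannot establish the exposure of interest.
    """
    if not drug_names:
        raise ValueError("drug_names must be non-empty")
    route = Route(route)
    names = {n.lower() for n in drug_names}
    out = []
    for r in reports:
        for d in r.drugs:
            if d.drug_name.lower() not in names:
                continue
            if require_suspected and d.role is not DrugRole.suspected:
                continue
            if d.route is route and route is not Route.unreported:
                out.append(r)
                break
    return out


def filter_period(
    reports: Iterable[ICSR], start: dt.date, end: dt.date
) -> list[ICSR]:
    """Reports with start <= report_date <= end (closed interval)."""
    if start > end:
        raise ValueError(f"start {start} after end {end}")
    return [r for r in reports if start <= r.report_date <= end]


def filter_age(
    reports: Iterable[ICSR],
    min_age: float,
    max_age: float | None = None,
    max_exclusive: bool = False,
) -> list[ICSR]:
    """Age-restricted cohort; reports with missing age are excluded.

    ``max_age`` is inclusive by default; set ``max_exclusive`` for
    closed-open bands (e.g. [65, 75) for a "65-74 years" band that must
    tile disjointly with ">=75").
    """
    if min_age < 0:
        raise ValueError("min_age must be >= 0")
    out = []
    for r in reports:
        if r.age_years is None or r.age_years < min_age:
            continue
        if max_age is not None:
            if max_exclusive and r.age_years >= max_age:
                continue
            if not max_exclusive and r.age_years > max_age:
                continue
        out.append(r)
    return out


def filter_sex(reports: Iterable[ICSR], sex: Sex | str) -> list[ICSR]:
    """Reports of the given sex; missing sex is excluded."""
    sex = Sex(sex)
    return [r for r in reports if r.sex is sex]
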