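"""Spontaneous adverse-event report data model and tabular I/O.

One :class:`AdverseEventReport` is an individual case: the drugs mentioned on
the report (suspect or concomitant role), the coded reaction terms, and the
reporter metadata that spontaneous-reporting systems such as FAERS collect
(reporter type, age, sex, country, event year, literature-reference flag).
A :class:`ReportSet` is the analyzable database.

Two lossless on-disk dialects are supported:

* CSV — one row per report, multi-valued cells joined with ``"|"``,
  ``reasons_for_use`` aligned positionally with ``suspect_drugs``;
* JSONL — one JSON object per line, drugs as ``{name, role, reason_for_use}``.

Normalization is deliberately minimal: drug names are uppercased with
whitespace collapsed (active-ingredient granularity, no salt/ingredient
thesaurus), reaction terms are casefolded, and matching against an index
term is exact equality on the normalized preferred term — no substring or
dictionary-hierarchy matching.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

logger = logging.getLogger(__name__)

__all__ = [
    "DrugRole",
    "Seriousness",
    "Sex",
    "ReporterType",
    "ReportFormat",
    "DrugMention",
    "AdverseEventReport",
    "ReportSet",
    "FormatError",
    "ValidationError",
    "normalize_drug_name",
    "normalize_term",
    "matches_term",
    "read_reports",
    "write_reports",
    "CSV_COLUMNS",
]

MULTI_VALUE_SEP = "|"

CSV_COLUMNS = [
    "report_id",
    "suspect_drugs",
    "concomitant_drugs",
    "reactions",
    "reasons_for_use",
    "seriousness",
    "event_year",
    "sex",
    "age_years",
    "weight_kg",
    "reporter_type",
    "country",
    "has_literature_ref",
]


class FormatError(ValueError):
    """The on-disk file does not conform to the declared dialect."""


class ValidationError(ValueError):
    """One or more records violate the data-model invariants."""

    def __init__(self, message: str, errors: Optional[list[str]] = None):
        super().__init__(message)
        self.errors = errors or []


class DrugRole(str, Enum):
    SUSPECT = "SUSPECT"
    CONCOMITANT = "CONCOMITANT"


class Seriousness(str, Enum):
    SERIOUS = "SERIOUS"
    NON_SERIOUS = "NON_SERIOUS"


class Sex(str, Enum):
    M = "M"
    F = "F"
    UNKNOWN = "UNKNOWN"


class ReporterType(str, Enum):
    CONSUMER = "CONSUMER"
    HEALTHCARE_PROFESSIONAL = "HEALTHCARE_PROFESSIONAL"
    UNKNOWN = "UNKNOWN"


class ReportFormat(str, Enum):
    CSV = "CSV"
    JSONL = "JSONL"


def normalize_drug_name(name: str) -> str:
    """Uppercase and collapse internal whitespace; no ingredient mapping."""
    return " ".join(str(name).split()).upper()


def normalize_term(term: str) -> str:
    """Case-normalize a reaction / MedDRA preferred term for exact matching."""
    return " ".join(str(term).split()).casefold()


@dataclass(frozen=True)
class DrugMention:
    """A drug named on a report, with its role and (optional) reason for use."""

    drug_name: str
    role: DrugRole
    reason_for_use: Optional[str] = None

    def __post_init__(self):
        name = normalize_drug_name(self.drug_name)
        if not name:
            raise ValidationError("drug_name is empty after normalization")
        if MULTI_VALUE_SEP in name:
            raise ValidationError(f"drug_name may not contain {MULTI_VALUE_SEP!r}: {name!r}")
        object.__setattr__(self, "drug_name", name)
        object.__setattr__(self, "role", DrugRole(self.role))
        reason = self.reason_for_use
        if reason is not None:
            reason = " ".join(str(reason).split())
            if not reason:
                reason = None
            elif MULTI_VALUE_SEP in reason:
                raise ValidationError(f"reason_for_use may not contain {MULTI_VALUE_SEP!r}")
        object.__setattr__(self, "reason_for_use", reason)


@dataclass(frozen=True)
class AdverseEventReport:
    """One individual case (the counting unit of disproportionality analysis)."""

    report_id: str
    drugs: tuple[DrugMention, ...]
    reactions: tuple[str, ...]
    seriousness: Optional[Seriousness] = None
    event_year: Optional[int] = None
    sex: Optional[Sex] = None
    age_years: Optional[float] = None
    weight_kg: Optional[float] = None
    reporter_type: ReporterType = ReporterType.UNKNOWN
    country: Optional[str] = None
    has_literature_ref: bool = False

    def __post_init__(self):
        rid = str(self.report_id).strip()
        if not rid:
            raise ValidationError("report_id is empty")
        object.__setattr__(self, "report_id", rid)

        drugs = tuple(self.drugs)
        if not drugs:
            raise ValidationError(f"report {rid}: at least one drug mention required")
        if not any(d.role is DrugRole.SUSPECT for d in drugs):
            raise ValidationError(f"report {rid}: at least one SUSPECT drug required")
        object.__setattr__(self, "drugs", drugs)

        reactions = tuple(normalize_term(r) for r in self.reactions)
        if not reactions or any(not r for r in reactions):
            raise ValidationError(f"report {rid}: reactions must be non-empty")
        if any(MULTI_VALUE_SEP in r for r in reactions):
            raise ValidationError(f"report {rid}: reaction terms may not contain {MULTI_VALUE_SEP!r}")
        object.__setattr__(self, "reactions", reactions)

        if self.seriousness is not None:
            object.__setattr__(self, "seriousness", Seriousness(self.seriousness))
        if self.sex is not None:
            object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "reporter_type", ReporterType(self.reporter_type))

        if self.event_year is not None:
            object.__setattr__(self, "event_year", int(self.event_year))
        if self.age_years is not None:
            age = float(self.age_years)
            if not (0.0 <= age <= 130.0):
                raise ValidationError(f"report {rid}: age_years {age} outside [0, 130]")
            object.__setattr__(self, "age_years", age)
        if self.weight_kg is not None:
            w = float(self.weight_kg)
            if w < 0:
                raise ValidationError(f"report {rid}: weight_kg {w} negative")
            object.__setattr__(self, "weight_kg", w)
        if self.country is not None:
            country = str(self.country).strip().upper()
            object.__setattr__(self, "country", country or None)
        object.__setattr__(self, "has_literature_ref", bool(self.has_literature_ref))

    # -- convenience accessors used throughout the analysis modules --

    @property
    def suspect_names(self) -> tuple[str, ...]:
        return tuple(d.drug_name for d in self.drugs if d.role is DrugRole.SUSPECT)

    @property
    def concomitant_names(self) -> tuple[str, ...]:
        return tuple(d.drug_name for d in self.drugs if d.role is DrugRole.CONCOMITANT)

    @property
    def has_concomitant(self) -> bool:
        return any(d.role is DrugRole.CONCOMITANT for d in self.drugs)

    def is_suspect(self, drug: str) -> bool:
        return normalize_drug_name(drug) in self.suspect_names

    def reason_for(self, drug: str) -> Optional[str]:
        """Reason for use attached to the first suspect mention of *drug*."""
        name = normalize_drug_name(drug)
        for d in self.drugs:
            if d.role is DrugRole.SUSPECT and d.drug_name == name:
                return d.reason_for_use
        return None


def matches_term(report: AdverseEventReport, term: str) -> bool:
    """Exact (case/whitespace-insensitive) preferred-term membership test.

    Deliberately not a substring or hierarchy match: an index query for
    "Infertility male" must not pick up related terms such as
    "Oligozoospermia" that code mere semen-parameter alterations.
    """
    t = normalize_term(term)
    if not t:
        raise ValueError("term is empty")
    return t in report.reactions


@dataclass(frozen=True)
class ReportSet:
    """An ordered, duplicate-free collection of reports (the database)."""

    reports: tuple[AdverseEventReport, ...]
    provenance: str = ""

    def __post_init__(self):
        reports = tuple(self.reports)
        object.__setattr__(self, "reports", reports)
        seen: dict[str, int] = {}
        dups = []
        for r in reports:
            if r.report_id in seen:
                dups.append(r.report_id)
            seen[r.report_id] = 1
        if dups:
            raise ValidationError(
                f"duplicate report_id(s): {sorted(set(dups))}", errors=sorted(set(dups))
            )

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[AdverseEventReport]:
        return iter(self.reports)

    def __getitem__(self, i):
        return self.reports[i]

    def filter(self, predicate, provenance: Optional[str] = None) -> "ReportSet":
        kept = tuple(r for r in self.reports if predicate(r))
        return ReportSet(kept, provenance if provenance is not None else self.provenance)


# --------------------------------------------------------------------------
# serialization


def _join(values: Sequence[str]) -> str:
    return MULTI_VALUE_SEP.join(values)


def _split(cell: str) -> list[str]:
    if cell == "":
        return []
    return cell.split(MULTI_VALUE_SEP)


def _report_to_row(r: AdverseEventReport) -> dict[str, str]:
    suspects = [d for d in r.drugs if d.role is DrugRole.SUSPECT]
    concomitants = [d for d in r.drugs if d.role is DrugRole.CONCOMITANT]
    return {
        "report_id": r.report_id,
        "suspect_drugs": _join([d.drug_name for d in suspects]),
        "concomitant_drugs": _join([d.drug_name for d in concomitants]),
        "reactions": _join(r.reactions),
        "reasons_for_use": _join([d.reason_for_use or "" for d in suspects]),
        "seriousness": r.seriousness.value if r.seriousness else "",
        "event_year": "" if r.event_year is None else str(r.event_year),
        "sex": r.sex.value if r.sex else "",
        "age_years": "" if r.age_years is None else repr(r.age_years),
        "weight_kg": "" if r.weight_kg is None else repr(r.weight_kg),
        "reporter_type": r.reporter_type.value,
        "country": r.country or "",
        "has_literature_ref": "true" if r.has_literature_ref else "false",
    }


def _row_to_report(row: dict[str, str]) -> AdverseEventReport:
    suspects = _split(row["suspect_drugs"])
    reasons = _split(row["reasons_for_use"])
    if reasons and len(reasons) != len(suspects):
        raise ValidationError(
            f"report {row.get('report_id', '?')}: reasons_for_use has "
            f"{len(reasons)} entries for {len(suspects)} suspect drugs"
        )
    if not reasons:
        reasons = [""] * len(suspects)
    drugs = [
        DrugMention(name, DrugRole.SUSPECT, reason or None)
        for name, reason in zip(suspects, reasons)
    ]
    drugs += [DrugMention(name, DrugRole.CONCOMITANT) for name in _split(row["concomitant_drugs"])]

    def opt(key, conv):
        cell = row.get(key, "").strip()
        return conv(cell) if cell else None

    return AdverseEventReport(
        report_id=row["report_id"],
        drugs=tuple(drugs),
        reactions=tuple(_split(row["reactions"])),
        seriousness=opt("seriousness", Seriousness),
        event_year=opt("event_year", int),
        sex=opt("sex", Sex),
        age_years=opt("age_years", float),
        weight_kg=opt("weight_kg", float),
        reporter_type=ReporterType(row.get("reporter_type") or "UNKNOWN"),
        country=opt("country", str),
        has_literature_ref=row.get("has_literature_ref", "false").strip().lower()
        in ("true", "1", "yes"),
    )


def _report_to_obj(r: AdverseEventReport) -> dict:
    return {
        "report_id": r.report_id,
        "drugs": [
            {"name": d.drug_name, "role": d.role.value, "reason_for_use": d.reason_for_use}
            for d in r.drugs
        ],
        "reactions": list(r.reactions),
        "seriousness": r.seriousness.value if r.seriousness else None,
        "event_year": r.event_year,
        "sex": r.sex.value if r.sex else None,
        "age_years": r.age_years,
        "weight_kg": r.weight_kg,
        "reporter_type": r.reporter_type.value,
        "country": r.country,
        "has_literature_ref": r.has_literature_ref,
    }


def _obj_to_report(obj: dict) -> AdverseEventReport:
    drugs = tuple(
        DrugMention(d["name"], DrugRole(d["role"]), d.get("reason_for_use"))
        for d in obj["drugs"]
    )
    return AdverseEventReport(
        report_id=obj["report_id"],
        drugs=drugs,
        reactions=tuple(obj["reactions"]),
        seriousness=Seriousness(obj["seriousness"]) if obj.get("seriousness") else None,
        event_year=obj.get("event_year"),
        sex=Sex(obj["sex"]) if obj.get("sex") else None,
        age_years=obj.get("age_years"),
        weight_kg=obj.get("weight_kg"),
        reporter_type=ReporterType(obj.get("reporter_type") or "UNKNOWN"),
        country=obj.get("country"),
        has_literature_ref=bool(obj.get("has_literature_ref", False)),
    )


def _coerce_format(fmt: Union[str, ReportFormat]) -> ReportFormat:
    if isinstance(fmt, ReportFormat):
        return fmt
    return ReportFormat(str(fmt).upper())


def read_reports(
    path: Union[str, Path],
    format: Union[str, ReportFormat] = ReportFormat.CSV,
    on_invalid: str = "raise",
) -> ReportSet:
    """Read a :class:`ReportSet` from CSV or JSONL.

    Parameters
    ----------
    path
        Input file. An empty file yields an empty ReportSet.
    format
        ``"CSV"`` or ``"JSONL"``.
    on_invalid
        ``"raise"`` (default) aborts with a :class:`ValidationError` listing
        every offending row; ``"skip"`` drops invalid rows, logging each one.

    Raises
    ------
    FormatError
        Missing mandatory column (CSV) or unparseable line (JSONL).
    ValidationError
        Invariant violations (including duplicate ``report_id``).
    """
    if on_invalid not in ("raise", "skip"):
        raise ValueError("on_invalid must be 'raise' or 'skip'")
    path = Path(path)
    fmt = _coerce_format(format)

    reports: list[AdverseEventReport] = []
    errors: list[str] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        if fmt is ReportFormat.CSV:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:  # zero-byte file
                return ReportSet((), provenance=str(path))
            missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
            rows = enumerate(reader, start=2)
            for lineno, row in rows:
                try:
                    reports.append(_row_to_report(row))
                except (ValidationError, ValueError) as exc:
                    errors.append(f"line {lineno}: {exc}")
        else:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise FormatError(f"line {lineno}: invalid JSON: {exc}") from exc
                try:
                    reports.append(_obj_to_report(obj))
                except (ValidationError, ValueError, KeyError) as exc:
                    errors.append(f"line {lineno}: {exc}")

    if errors:
        if on_invalid == "raise":
            raise ValidationError(
                f"{len(errors)} invalid row(s) in {path}:\n" + "\n".join(errors), errors=errors
            )
        for e in errors:
            logger.warning("skipping invalid row (%s): %s", path, e)

    ids = [r.report_id for r in reports]
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        raise ValidationError(f"duplicate report_id(s): {sorted(dups)}", errors=sorted(dups))

    return ReportSet(tuple(reports), provenance=str(path))


def write_reports(
    rs: ReportSet,
    path: Union[str, Path],
    format: Union[str, ReportFormat] = ReportFormat.CSV,
) -> None:
    """Write a ReportSet losslessly; ``read_reports`` inverts it field-by-field."""
    path = Path(path)
    fmt = _coerce_format(format)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if fmt is ReportFormat.CSV:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
            writer.writeheader()
            for r in rs:
                writer.writerow(_report_to_row(r))
        else:
            for r in rs:
                fh.write(json.dumps(_report_to_obj(r)) + "\n")
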