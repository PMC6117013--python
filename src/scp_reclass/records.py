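"""Domain types, invariant checking and CSV readers/writers.

Three linked record streams feed the pipeline: perinatal (delivery)
records carrying the maternal smoking items, hospital separation records
carrying ICD-10-AM diagnosis codes, and pharmaceutical dispensing claims
carrying ATC-coded supplies.  All records are plain frozen dataclasses;
dates are calendar dates (``datetime.date``) because every source carries
day resolution only.  A fourth derived type, :class:`PregnancyEpisode`,
adds the conception date and the 100-day pre-conception lookback window.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

__all__ = [
    "TherapySpec",
    "DispensingRecord",
    "PerinatalRecord",
    "HospitalSeparation",
    "PregnancyEpisode",
    "DEFAULT_CATALOG",
    "load_catalog",
    "read_records",
    "write_records",
    "derive_episode",
    "RecordError",
    "SchemaError",
    "InvariantError",
]

LOOKBACK_DAYS = 100  # pre-conception dispensing lookback window

MAX_DIAGNOSIS_FIELDS = 55  # widest of the two state collections


class SchemaError(ValueError):
    """Header or token does not match the declared CSV schema."""


class InvariantError(ValueError):
    """A parsed record violates a domain invariant."""


@dataclass(frozen=True)
class RecordError:
    """One rejected input row: its 1-based row number, column and reason."""

    row: int
    column: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - formatting only
        return f"row {self.row}, column {self.column!r}: {self.message}"


@dataclass(frozen=True)
class TherapySpec:
    """Constants for one smoking cessation pharmacotherapy.

    ``doses_per_day`` converts dispensed quantity to days covered,
    ``min_course_days`` is the minimum recommended course for cessation,
    ``lead_time_days`` the recommended pre-quit-date lead time, and
    ``listing_date`` the date the product became subsidised (defines the
    utilisation measurement era).
    """

    atc_code: str
    name: str
    doses_per_day: int
    min_course_days: int
    lead_time_days: int
    listing_date: date

    def __post_init__(self) -> None:
        if self.doses_per_day not in (1, 2):
            raise InvariantError(f"doses_per_day must be 1 or 2, got {self.doses_per_day}")
        if self.min_course_days <= 0:
            raise InvariantError("min_course_days must be positive")
        if self.lead_time_days <= 0:
            raise InvariantError("lead_time_days must be positive")


#: Built-in therapy catalog: NRT patches (once daily, 8-week course,
#: 2-week lead), bupropion and varenicline (twice daily, 7- and 12-week
#: courses, 1-week lead), with their subsidy listing dates.
DEFAULT_CATALOG: dict[str, TherapySpec] = {
    "N07BA01": TherapySpec("N07BA01", "nrt", 1, 56, 14, date(2011, 2, 1)),
    "N07BA02": TherapySpec("N07BA02", "bupropion", 2, 49, 7, date(2001, 2, 1)),
    "N07BA03": TherapySpec("N07BA03", "varenicline", 2, 84, 7, date(2008, 1, 10)),
}


def load_catalog(path: str | Path) -> dict[str, TherapySpec]:
    """Load a therapy catalog from YAML/JSON, overriding the defaults.

    The file maps ATC code to a mapping with keys ``name``,
    ``doses_per_day``, ``min_course_days``, ``lead_time_days`` and
    ``listing_date`` (ISO date).  Codes absent from the file keep their
    built-in definition.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    catalog = dict(DEFAULT_CATALOG)
    for atc, entry in raw.items():
        listing = entry["listing_date"]
        if isinstance(listing, str):
            listing = date.fromisoformat(listing)
        catalog[atc] = TherapySpec(
            atc_code=atc,
            name=entry["name"],
            doses_per_day=int(entry["doses_per_day"]),
            min_course_days=int(entry["min_course_days"]),
            lead_time_days=int(entry["lead_time_days"]),
            listing_date=listing,
        )
    return catalog


@dataclass(frozen=True)
class DispensingRecord:
    """One subsidised dispensing claim."""

    woman_id: str
    supply_date: date
    atc_code: str
    quantity: float
    concession_status: str  # "general" | "concessional"

    def check(self) -> None:
        if self.quantity <= 0:
            raise InvariantError(f"quantity must be > 0, got {self.quantity}")
        if self.concession_status not in ("general", "concessional"):
            raise InvariantError(
                f"concession_status must be general/concessional, got {self.concession_status!r}"
            )


@dataclass(frozen=True)
class PerinatalRecord:
    """One delivery record with maternal smoking items and demographics.

    Two reporting dialects exist: an any-time-in-pregnancy item
    (``smoked_any``) in the earlier collection era and half-of-pregnancy
    items (``smoked_first_half`` / ``smoked_second_half``) afterwards.
    Exactly one dialect is populated per record; the trivalent values are
    ``True`` (yes), ``False`` (no) and ``None`` (missing).
    """

    pregnancy_id: str
    woman_id: str
    delivery_date: date
    gestation_weeks: int
    smoked_any: Optional[bool]
    smoked_first_half: Optional[bool]
    smoked_second_half: Optional[bool]
    maternal_age: int
    marital_status: str  # "married" | "not_married"
    seifa_quintile: Optional[int]  # 1..5, None if missing
    hospital_type: str  # "private" | "public"
    state: str  # "NSW" | "WA"

    def check(self) -> None:
        if not 20 <= self.gestation_weeks <= 45:
            raise InvariantError(
                f"gestation_weeks must be in [20, 45], got {self.gestation_weeks}"
            )
        any_dialect = self.smoked_any is not None
        half_dialect = self.smoked_first_half is not None or self.smoked_second_half is not None
        if any_dialect and half_dialect:
            raise InvariantError("both smoking-item dialects populated")
        if self.marital_status not in ("married", "not_married"):
            raise InvariantError(f"bad marital_status {self.marital_status!r}")
        if self.seifa_quintile is not None and not 1 <= self.seifa_quintile <= 5:
            raise InvariantError(f"seifa_quintile must be 1..5, got {self.seifa_quintile}")
        if self.hospital_type not in ("private", "public"):
            raise InvariantError(f"bad hospital_type {self.hospital_type!r}")
        if self.state not in ("NSW", "WA"):
            raise InvariantError(f"bad state {self.state!r}")


@dataclass(frozen=True)
class HospitalSeparation:
    """One hospital separation (discharge/transfer/death) with diagnoses."""

    woman_id: str
    admission_date: date
    separation_date: date
    diagnosis_codes: tuple[str, ...]

    def check(self) -> None:
        if self.admission_date > self.separation_date:
            raise InvariantError("admission_date after separation_date")
        if len(self.diagnosis_codes) > MAX_DIAGNOSIS_FIELDS:
            raise InvariantError(
                f"more than {MAX_DIAGNOSIS_FIELDS} diagnosis codes"
            )


@dataclass(frozen=True)
class PregnancyEpisode:
    """A pregnancy with derived conception date and exposure window.

    Conception is imputed from completed gestation weeks as
    ``delivery_date - 7*gestation_weeks + 14`` days (last menstrual
    period plus two weeks); the dispensing ascertainment window runs from
    ``lookback_start = conception_date - 100`` days to the delivery.
    """

    pregnancy_id: str
    woman_id: str
    delivery_date: date
    gestation_weeks: int
    conception_date: date
    lookback_start: date
    maternal_age: int
    marital_status: str
    seifa_quintile: Optional[int]
    hospital_type: str
    state: str

    def check(self) -> None:
        expected = self.delivery_date - timedelta(days=7 * self.gestation_weeks - 14)
        if self.conception_date != expected:
            raise InvariantError("conception_date inconsistent with gestation")
        if self.lookback_start != self.conception_date - timedelta(days=LOOKBACK_DAYS):
            raise InvariantError("lookback_start inconsistent with conception_date")
        if not self.lookback_start < self.conception_date < self.delivery_date:
            raise InvariantError("episode window ordering violated")


def derive_episode(p: PerinatalRecord) -> PregnancyEpisode:
    """Derive the pregnancy episode (conception date, lookback window).

    Raises :class:`InvariantError` if gestation is outside [20, 45]
    completed weeks.
    """
    if not 20 <= p.gestation_weeks <= 45:
        raise InvariantError(
            f"gestation_weeks must be in [20, 45], got {p.gestation_weeks}"
        )
    conception = p.delivery_date - timedelta(days=7 * p.gestation_weeks - 14)
    episode = PregnancyEpisode(
        pregnancy_id=p.pregnancy_id,
        woman_id=p.woman_id,
        delivery_date=p.delivery_date,
        gestation_weeks=p.gestation_weeks,
        conception_date=conception,
        lookback_start=conception - timedelta(days=LOOKBACK_DAYS),
        maternal_age=p.maternal_age,
        marital_status=p.marital_status,
        seifa_quintile=p.seifa_quintile,
        hospital_type=p.hospital_type,
        state=p.state,
    )
    episode.check()
    return episode


# ---------------------------------------------------------------------------
# CSV serialisation
# ---------------------------------------------------------------------------

_TRIVALENT_IN = {"Y": True, "N": False, "": None}
_TRIVALENT_OUT = {True: "Y", False: "N", None: ""}

SCHEMAS: dict[str, type] = {
    "dispensing": DispensingRecord,
    "perinatal": PerinatalRecord,
    "hospital": HospitalSeparation,
    "episodes": PregnancyEpisode,
}

_HEADERS = {kind: [f.name for f in fields(cls)] for kind, cls in SCHEMAS.items()}


def _parse_date(token: str, row: int, column: str) -> date:
    try:
        return date.fromisoformat(token)
    except ValueError as exc:
        raise SchemaError(f"row {row}, column {column!r}: bad date {token!r}") from exc


def _parse_trivalent(token: str, row: int, column: str) -> Optional[bool]:
    token = token.strip()
    if token not in _TRIVALENT_IN:
        raise SchemaError(
            f"row {row}, column {column!r}: expected Y/N/blank, got {token!r}"
        )
    return _TRIVALENT_IN[token]


def _row_to_record(kind: str, row: dict[str, str], rownum: int):
    if kind == "dispensing":
        return DispensingRecord(
            woman_id=row["woman_id"],
            supply_date=_parse_date(row["supply_date"], rownum, "supply_date"),
            atc_code=row["atc_code"].strip(),
            quantity=float(row["quantity"]),
            concession_status=row["concession_status"].strip(),
        )
    if kind == "perinatal":
        seifa = row["seifa_quintile"].strip()
        return PerinatalRecord(
            pregnancy_id=row["pregnancy_id"],
            woman_id=row["woman_id"],
            delivery_date=_parse_date(row["delivery_date"], rownum, "delivery_date"),
            gestation_weeks=int(row["gestation_weeks"]),
            smoked_any=_parse_trivalent(row["smoked_any"], rownum, "smoked_any"),
            smoked_first_half=_parse_trivalent(
                row["smoked_first_half"], rownum, "smoked_first_half"
            ),
            smoked_second_half=_parse_trivalent(
                row["smoked_second_half"], rownum, "smoked_second_half"
            ),
            maternal_age=int(row["maternal_age"]),
            marital_status=row["marital_status"].strip(),
            seifa_quintile=int(seifa) if seifa else None,
            hospital_type=row["hospital_type"].strip(),
            state=row["state"].strip(),
        )
    if kind == "hospital":
        codes = tuple(c.strip() for c in row["diagnosis_codes"].split(";") if c.strip())
        return HospitalSeparation(
            woman_id=row["woman_id"],
            admission_date=_parse_date(row["admission_date"], rownum, "admission_date"),
            separation_date=_parse_date(row["separation_date"], rownum, "separation_date"),
            diagnosis_codes=codes,
        )
    if kind == "episodes":
        seifa = row["seifa_quintile"].strip()
        return PregnancyEpisode(
            pregnancy_id=row["pregnancy_id"],
            woman_id=row["woman_id"],
            delivery_date=_parse_date(row["delivery_date"], rownum, "delivery_date"),
            gestation_weeks=int(row["gestation_weeks"]),
            conception_date=_parse_date(row["conception_date"], rownum, "conception_date"),
            lookback_start=_parse_date(row["lookback_start"], rownum, "lookback_start"),
            maternal_age=int(row["maternal_age"]),
            marital_status=row["marital_status"].strip(),
            seifa_quintile=int(seifa) if seifa else None,
            hospital_type=row["hospital_type"].strip(),
            state=row["state"].strip(),
        )
    raise SchemaError(f"unknown schema kind {kind!r}")


def _record_to_row(kind: str, rec) -> dict[str, str]:
    row: dict[str, str] = {}
    for name in _HEADERS[kind]:
        value = getattr(rec, name)
        if isinstance(value, date):
            row[name] = value.isoformat()
        elif name.startswith("smoked_"):
            row[name] = _TRIVALENT_OUT[value]
        elif name == "diagnosis_codes":
            row[name] = ";".join(value)
        elif name == "quantity":
            row[name] = format(value, "g")
        elif value is None:
            row[name] = ""
        else:
            row[name] = str(value)
    return row


def read_records(
    path: str | Path, schema: str, strict: bool = True
) -> tuple[list, list[RecordError]]:
    """Read one of the four CSV schemas into typed records.

    Returns ``(records, errors)``; rows violating invariants are reported
    with their 1-based data row number.  With ``strict=True`` (default) a
    non-empty error list raises :class:`InvariantError`.  A header that
    does not match the schema, a malformed date or an unknown trivalent
    token raises :class:`SchemaError` immediately.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema kind {schema!r}")
    records: list = []
    errors: list[RecordError] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        expected = _HEADERS[schema]
        if reader.fieldnames != expected:
            raise SchemaError(
                f"{path}: header {reader.fieldnames} does not match schema "
                f"{schema!r} (expected {expected})"
            )
        for rownum, row in enumerate(reader, start=1):
            try:
                rec = _row_to_record(schema, row, rownum)
                if hasattr(rec, "check"):
                    rec.check()
            except InvariantError as exc:
                errors.append(RecordError(rownum, schema, str(exc)))
                continue
            except (KeyError, ValueError) as exc:
                if isinstance(exc, SchemaError):
                    raise
                errors.append(RecordError(rownum, schema, str(exc)))
                continue
            records.append(rec)
    if strict and errors:
        detail = "; ".join(str(e) for e in errors[:5])
        raise InvariantError(f"{path}: {len(errors)} invalid rows ({detail} ...)")
    return records, errors


def write_records(path: str | Path, records: Sequence, schema: str) -> None:
    """Write typed records to CSV with the documented header."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema kind {schema!r}")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_HEADERS[schema])
        writer.writeheader()
        for rec in records:
            writer.writerow(_record_to_row(schema, rec))
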