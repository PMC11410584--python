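"""REDCap-export-to-SQLite ingestion (the clinical-data pipeline).

A REDCap longitudinal project exports one CSV in which each row is keyed by
``(record_id, redcap_event_name, redcap_repeat_instrument,
redcap_repeat_instance)``. Declarative mapping files route each source field of
each instrument to a table/column of the canonical schema, optionally through
a cleaning rule (regex substitution, decimal or date normalisation, code-to-
label translation) and a validation rule (type, range, vocabulary). Whole
target rows either ingest cleanly or are rejected as a unit; rejections are
collected in a report and never abort the batch. Re-running an identical
export is a no-op (rows are upserted on their source key).
"""

from __future__ import annotations

import csv
import json
import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import schema as _schema
from .errors import FormatError, MappingError

# Longitudinal key columns of the REDCap CSV dialect.
RECORD_ID = "record_id"
EVENT = "redcap_event_name"
REPEAT_INSTRUMENT = "redcap_repeat_instrument"
REPEAT_INSTANCE = "redcap_repeat_instance"

CLEANING_KINDS = (
    "identity",
    "regex-substitute",
    "decimal-normalize",
    "date-normalize",
    "code-to-label",
)

#: Intra-row parent links: when one instrument row fans out into several
#: tables, the child table's foreign key is wired to the parent row created
#: from the same source row.
PARENT_LINK: dict[str, tuple[str, str]] = {
    "Medications": ("general_id", "ClinicalDataGeneral"),
    "Stimulations": ("stim_session_id", "StimulationSessions"),
    "StimulationEffects": ("stimulation_id", "Stimulations"),
    "StimulationSideEffects": ("stimulation_id", "Stimulations"),
    "MerTracks": ("mer_session_id", "MerSessions"),
    "MerDepths": ("mer_track_id", "MerTracks"),
    "ArcSettings": ("targeting_id", "TargetingPlans"),
    "PlannedTrajectories": ("targeting_id", "TargetingPlans"),
    "ChronicContacts": ("chronic_id", "ChronicSettings"),
    "ImplantedContacts": ("implanted_id", "ImplantedPositions"),
}

#: Insertion order respecting foreign-key dependencies.
TABLE_ORDER = (
    "Patients",
    "ClinicalDataGeneral",
    "Medications",
    "ClinicalEvalTremor",
    "ClinicalEvalUpdrs",
    "ClinicalEvalQol",
    "PostopScreenings",
    "ImagingAcquisitions",
    "StimulationSessions",
    "Stimulations",
    "StimulationEffects",
    "StimulationSideEffects",
    "MerSessions",
    "MerTracks",
    "MerDepths",
    "TargetingPlans",
    "ArcSettings",
    "PlannedTrajectories",
    "ChronicSettings",
    "ChronicContacts",
    "ImplantedPositions",
    "ImplantedContacts",
)

#: Tables whose rows link straight to the central patient table.
PATIENT_LINKED = {
    "ClinicalDataGeneral",
    "ClinicalEvalTremor",
    "ClinicalEvalUpdrs",
    "ClinicalEvalQol",
    "PostopScreenings",
    "ImagingAcquisitions",
    "StimulationSessions",
    "MerSessions",
    "TargetingPlans",
    "ChronicSettings",
    "ImplantedPositions",
}


@dataclass(frozen=True)
class CleaningRule:
    """One deterministic text-cleaning step applied before validation."""

    kind: str = "identity"
    pattern: str | None = None
    replacement: str | None = None
    format: str | None = None
    codes: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in CLEANING_KINDS:
            raise MappingError(f"unknown cleaning kind {self.kind!r}")
        if self.kind == "regex-substitute":
            if self.pattern is None:
                raise MappingError("regex-substitute requires a pattern")
            re.compile(self.pattern)
        if self.kind == "code-to-label":
            if not self.codes:
                raise MappingError("code-to-label requires a code table")
            labels = list(self.codes.values())
            if len(set(labels)) != len(labels):
                raise MappingError("code-to-label table must be injective")


@dataclass(frozen=True)
class MappingEntry:
    instrument: str
    field: str
    table: str
    column: str
    clean: CleaningRule = CleaningRule()
    validate: dict = None  # type: ignore[assignment]
    required: bool = False

    def __post_init__(self) -> None:
        if self.validate is None:
            object.__setattr__(self, "validate", {})


@dataclass
class MappingSpec:
    """Validated routing of REDCap instrument fields into schema columns."""

    instruments: list[str]
    entries: list[MappingEntry]

    def entries_for(self, instrument: str) -> list[MappingEntry]:
        return [e for e in self.entries if e.instrument == instrument]


@dataclass
class RecordSet:
    """Rows of a longitudinal export keyed by the four-part REDCap key."""

    rows: dict[tuple[str, str, str, str], dict[str, str]]
    columns: list[str]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class IngestReport:
    inserted: int = 0
    updated: int = 0
    rejected: int = 0
    rejections: list[tuple[str, str, str]] = field(default_factory=list)

    def reject(self, key: str, fieldname: str, reason: str) -> None:
        self.rejected += 1
        self.rejections.append((key, fieldname, reason))

    def to_json(self) -> str:
        return json.dumps(
            {
                "inserted": self.inserted,
                "updated": self.updated,
                "rejected": self.rejected,
                "rejections": [list(r) for r in self.rejections],
            },
            indent=2,
        )


# --- mapping files ---------------------------------------------------------


def load_mapping(path: str | Path, db: sqlite3.Connection | None = None) -> MappingSpec:
    """Parse and validate a YAML mapping file.

    With *db* given, every target table/column is additionally verified
    against the live schema before any data is touched.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise MappingError(f"cannot parse mapping file {path}: {exc}") from exc
    if not isinstance(doc, dict) or "entries" not in doc:
        raise MappingError(f"mapping file {path} lacks an 'entries' section")

    instruments = list(doc.get("instruments", []))
    if len(set(instruments)) != len(instruments):
        raise MappingError("instrument names must be unique")

    entries: list[MappingEntry] = []
    seen: set[tuple[str, str]] = set()
    for i, raw in enumerate(doc["entries"] or []):
        try:
            clean_doc = raw.get("clean") or {}
            entry = MappingEntry(
                instrument=raw["instrument"],
                field=raw["field"],
                table=raw["table"],
                column=raw["column"],
                clean=CleaningRule(**clean_doc) if clean_doc else CleaningRule(),
                validate=raw.get("validate") or {},
                required=bool(raw.get("required", False)),
            )
        except KeyError as exc:
            raise MappingError(f"entry {i}: missing key {exc}") from exc
        if entry.instrument not in instruments:
            raise MappingError(
                f"entry {i}: instrument {entry.instrument!r} not in the registry"
            )
        src = (entry.instrument, entry.field)
        if src in seen:
            raise MappingError(f"duplicate source field {src!r}")
        seen.add(src)
        entries.append(entry)

    spec = MappingSpec(instruments=instruments, entries=entries)
    if db is not None:
        validate_mapping(spec, db)
    else:
        known = set(_schema.canonical_tables())
        for e in spec.entries:
            if e.table not in known:
                raise MappingError(f"unknown target table {e.table!r}")
    return spec


def validate_mapping(spec: MappingSpec, db: sqlite3.Connection) -> None:
    """Check every target table/column against the live schema."""
    tables = set(_schema.user_tables(db))
    for e in spec.entries:
        if e.table not in tables:
            raise MappingError(f"unknown target table {e.table!r}")
        if e.column not in _schema.columns(db, e.table):
            raise MappingError(f"unknown target column {e.table}.{e.column!r}")


# --- value cleaning --------------------------------------------------------

_DATE_FORMATS = ("%Y-%m-%d", "%d.%m.%Y", "%d/%m/%Y")


def clean_value(
    raw: str, rule: CleaningRule, validation: dict | None = None
) -> tuple[object, str | None]:
    """Clean and validate one cell.

    Returns ``(value, None)`` on success, ``(None, None)`` for a missing
    (empty) cell, and ``(None, reason)`` on rejection. Never raises for bad
    data — rejections flow into the batch report.
    """
    validation = validation or {}
    text = (raw or "").strip()
    if text == "":
        return None, None

    if rule.kind == "regex-substitute":
        text = re.sub(rule.pattern, rule.replacement or "", text)
    elif rule.kind == "decimal-normalize":
        text = text.replace(" ", "").replace(",", ".")
    elif rule.kind == "date-normalize":
        from datetime import datetime

        formats = (rule.format,) if rule.format else _DATE_FORMATS
        for fmt in formats:
            try:
                text = datetime.strptime(text, fmt).strftime("%Y-%m-%d")
                break
            except ValueError:
                continue
        else:
            return None, f"not a date in any accepted format: {text!r}"
    elif rule.kind == "code-to-label":
        if text not in rule.codes:
            return None, f"unknown code {text!r}"
        text = rule.codes[text]

    value: object = text
    vtype = validation.get("type", "text")
    if vtype in ("number", "integer"):
        try:
            value = float(text)
        except ValueError:
            return None, "not numeric"
        if vtype == "integer":
            if value != int(value):
                return None, "not an integer"
            value = int(value)
    elif vtype == "date":
        if not re.fullmatch(r"\d{4}-\d{2}-\d{2}", text):
            return None, f"not an ISO date: {text!r}"

    if "min" in validation and value < validation["min"]:
        return None, f"below minimum {validation['min']}"
    if "max" in validation and value > validation["max"]:
        return None, f"above maximum {validation['max']}"
    if "choices" in validation and value not in validation["choices"]:
        return None, f"not in {validation['choices']}"
    if "max_length" in validation and len(str(value)) > validation["max_length"]:
        return None, "too long"
    return value, None


# --- export parsing --------------------------------------------------------


def parse_redcap_export(path: str | Path) -> RecordSet:
    """Read a longitudinal REDCap CSV export into a keyed RecordSet.

    Missing event/repeat columns are tolerated (classic non-repeating
    export); their key components default to the empty string.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if RECORD_ID not in header:
            raise FormatError(f"{path}: no {RECORD_ID!r} column")
        rows: dict[tuple[str, str, str, str], dict[str, str]] = {}
        for lineno, row in enumerate(reader, start=2):
            record = (row.get(RECORD_ID) or "").strip()
            if not record:
                raise FormatError(f"{path}:{lineno}: empty {RECORD_ID}")
            key = (
                record,
                (row.get(EVENT) or "").strip(),
                (row.get(REPEAT_INSTRUMENT) or "").strip(),
                (row.get(REPEAT_INSTANCE) or "").strip(),
            )
            if key in rows:
                raise FormatError(f"{path}:{lineno}: duplicate key tuple {key}")
            rows[key] = row
    return RecordSet(rows=rows, columns=list(header))


# --- ingestion -------------------------------------------------------------


def _key_str(key: tuple[str, str, str, str]) -> str:
    return "|".join(key)


def _instruments_for_row(
    key: tuple[str, str, str, str], row: dict[str, str], mapping: MappingSpec
) -> list[str]:
    """Instruments contributing to one export row.

    A repeating row names its instrument; a non-repeating row may carry the
    fields of several instruments of that event and contributes to every
    instrument with at least one non-empty mapped field.
    """
    repeat = key[2]
    if repeat:
        return [repeat] if repeat in mapping.instruments else []
    out = []
    for inst in mapping.instruments:
        for e in mapping.entries_for(inst):
            if (row.get(e.field) or "").strip():
                out.append(inst)
                break
    return out


def ingest(
    records: RecordSet, mapping: MappingSpec, db: sqlite3.Connection
) -> IngestReport:
    """Route a RecordSet into the database through a validated mapping.

    Per-value failures reject whole target rows (never half a clinical row)
    and are listed in the report; structural problems (unknown target
    columns) abort before any write. Upserts are keyed on the source key
    tuple, so identical re-runs insert and update nothing.
    """
    validate_mapping(mapping, db)
    report = IngestReport()

    # table -> entries grouped per instrument, in dependency order
    by_inst_table: dict[str, dict[str, list[MappingEntry]]] = {}
    for e in mapping.entries:
        by_inst_table.setdefault(e.instrument, {}).setdefault(e.table, []).append(e)

    sorted_keys = sorted(records.rows)
    # (row key, instrument, table) -> surrogate id of the row created/found
    made: dict[tuple[tuple[str, str, str, str], str, str], int] = {}
    rejected_rows: set[tuple[tuple[str, str, str, str], str, str]] = set()

    with db:
        for table in TABLE_ORDER:
            for key in sorted_keys:
                row = records.rows[key]
                for inst in _instruments_for_row(key, row, mapping):
                    entries = by_inst_table.get(inst, {}).get(table)
                    if not entries:
                        continue
                    _ingest_target_row(
                        db, table, inst, key, row, entries, made, rejected_rows, report
                    )
    return report


def _ingest_target_row(db, table, inst, key, row, entries, made, rejected, report):
    kstr = _key_str(key)
    values: dict[str, object] = {}
    errors: list[tuple[str, str]] = []
    any_present = False
    for e in entries:
        raw = row.get(e.field, "")
        value, err = clean_value(raw, e.clean, e.validate)
        if err is not None:
            errors.append((e.field, err))
            continue
        if value is None:
            if e.required:
                errors.append((e.field, "required field missing"))
            continue
        any_present = True
        values[e.column] = value

    if not any_present and not errors:
        return  # instrument row carries no data for this table
    if errors:
        for fieldname, reason in errors:
            report.rejections.append((kstr, fieldname, reason))
        report.rejected += 1
        rejected.add((key, inst, table))
        return

    pk = _schema.columns(db, table)[0]

    if table == "Patients":
        values["patient_code"] = key[0]
        existing = db.execute(
            "SELECT * FROM Patients WHERE patient_code = ?", (key[0],)
        ).fetchone()
    else:
        if table in PATIENT_LINKED:
            patient = _schema.get_patient(db, key[0])
            if patient is None:
                report.reject(kstr, "", f"no patient record for {key[0]!r}")
                rejected.add((key, inst, table))
                return
            values["patient_id"] = patient["patient_id"]
        if table in PARENT_LINK:
            fk_col, parent = PARENT_LINK[table]
            if (key, inst, parent) in rejected:
                report.reject(kstr, "", f"parent row in {parent} was rejected")
                rejected.add((key, inst, table))
                return
            parent_id = made.get((key, inst, parent))
            if parent_id is None:
                report.reject(kstr, "", f"no parent row in {parent}")
                rejected.add((key, inst, table))
                return
            values[fk_col] = parent_id
        source_key = f"{kstr}|{inst}|{table}"
        values["source_key"] = source_key
        existing = db.execute(
            f'SELECT * FROM "{table}" WHERE source_key = ?', (source_key,)
        ).fetchone()

    try:
        if existing is not None:
            changed = {c: v for c, v in values.items() if existing[c] != v}
            if changed:
                sets = ", ".join(f'"{c}" = ?' for c in changed)
                db.execute(
                    f'UPDATE "{table}" SET {sets} WHERE "{pk}" = ?',
                    (*changed.values(), existing[pk]),
                )
                report.updated += 1
            made[(key, inst, table)] = existing[pk]
            return

        cols = ", ".join(f'"{c}"' for c in values)
        marks = ", ".join("?" for _ in values)
        cur = db.execute(
            f'INSERT INTO "{table}" ({cols}) VALUES ({marks})', tuple(values.values())
        )
    except sqlite3.IntegrityError as exc:
        # e.g. a CHECK constraint the mapping's validation did not pre-empt
        report.reject(kstr, "", f"{table}: {exc}")
        rejected.add((key, inst, table))
        return
    report.inserted += 1
    made[(key, inst, table)] = cur.lastrowid
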