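"""Patient-centric relational schema for DBS research data.

The schema lives in ``schema.sql`` (shipped with the package) and is the single
source of truth: 28 tables organised into content groups (clinical data,
imaging data, stimulation-configuration evaluations, microelectrode
recordings, targeting, chronic stimulation configuration, implanted position,
electrodes) around a central ``Patients`` table. All structural numbers
reported by this module are obtained by catalog introspection of a live
database, never from constants.

The database is a single SQLite file. SQLite does not enforce foreign keys by
default, so every connection handed out by this module switches enforcement on.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import SchemaMismatchError

SCHEMA_VERSION = 1

#: PRAGMA application_id stamped into every database file created by this
#: package; used to recognise our own files.
APPLICATION_ID = 0x0DB5C0DB  # fits in SQLite's signed 32-bit pragma

SQLITE_MAGIC = b"SQLite format 3\x00"

#: Content groups of the schema. Every user table belongs to exactly one
#: group; all groups except Electrodes contain at least one table with a
#: direct foreign key to Patients.
TABLE_GROUPS: dict[str, tuple[str, ...]] = {
    "Central": ("Patients",),
    "ClinicalData": (
        "ClinicalDataGeneral",
        "Medications",
        "ClinicalEvalTremor",
        "ClinicalEvalUpdrs",
        "ClinicalEvalQol",
        "PostopScreenings",
        "ImagingAcquisitions",
    ),
    "ImagingData": ("Files", "Bids", "Labels", "Transformations"),
    "StimulationConfigurationEvaluation": (
        "StimulationSessions",
        "Stimulations",
        "StimulationEffects",
        "StimulationSideEffects",
    ),
    "MicroelectrodeRecordings": ("MerSessions", "MerTracks", "MerDepths"),
    "Targeting": ("TargetingPlans", "ArcSettings", "PlannedTrajectories"),
    "ChronicStimulationConfiguration": ("ChronicSettings", "ChronicContacts"),
    "ImplantedPosition": ("ImplantedPositions", "ImplantedContacts"),
    "Electrodes": ("Electrodes", "ElectrodeContactGeometry"),
}

DISEASES = ("ET", "PD", "other")
SEXES = ("F", "M", "other")


@dataclass(frozen=True)
class SchemaStats:
    """Structural summary of a database: table, column and foreign-key counts."""

    n_tables: int
    n_fields: int
    n_relationships: int


@dataclass(frozen=True)
class TableGroup:
    name: str
    member_tables: tuple[str, ...]


@dataclass
class PatientRecord:
    """Central clinical entity; all table groups except Electrodes link to it."""

    patient_code: str
    center: str
    disease: str
    sex: str | None = None
    age_at_surgery: float | None = None
    medical_history: str | None = None
    patient_id: int | None = None


@dataclass
class ElectrodeRecord:
    model_name: str
    manufacturer: str | None = None
    n_contacts: int | None = None
    lead_diameter_mm: float | None = None
    model_file_id: int | None = None
    electrode_id: int | None = None


@dataclass
class IntegrityReport:
    """Result of comparing a live database against the canonical schema."""

    missing_tables: list[str] = field(default_factory=list)
    unexpected_tables: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.missing_tables and not self.unexpected_tables


def ddl() -> str:
    """Return the canonical DDL script shipped with the package."""
    return resources.files(__package__).joinpath("schema.sql").read_text()


def canonical_tables() -> tuple[str, ...]:
    """All user table names, in no particular order."""
    return tuple(t for members in TABLE_GROUPS.values() for t in members)


def table_groups() -> list[TableGroup]:
    return [TableGroup(name, members) for name, members in TABLE_GROUPS.items()]


def _configure(conn: sqlite3.Connection) -> sqlite3.Connection:
    conn.execute("PRAGMA foreign_keys = ON")
    conn.row_factory = sqlite3.Row
    return conn


def init_db(path: str | Path) -> sqlite3.Connection:
    """Create (or re-open) the study database at *path*.

    Idempotent: running it on an already-initialized database changes nothing.
    A file that exists but is not a database created by this package raises
    :class:`SchemaMismatchError` and is left untouched.
    """
    path = Path(path)
    if path.exists() and path.stat().st_size > 0:
        with path.open("rb") as fh:
            if fh.read(16) != SQLITE_MAGIC:
                raise SchemaMismatchError(f"{path} exists and is not an SQLite database")
        conn = _configure(sqlite3.connect(path))
        app_id = conn.execute("PRAGMA application_id").fetchone()[0]
        has_tables = conn.execute(
            "SELECT count(*) FROM sqlite_master WHERE type='table'"
        ).fetchone()[0]
        if has_tables and app_id != APPLICATION_ID:
            conn.close()
            raise SchemaMismatchError(
                f"{path} is an SQLite database but was not created by this package"
            )
    else:
        conn = _configure(sqlite3.connect(path))

    with conn:
        conn.executescript(ddl())
        conn.execute(f"PRAGMA application_id = {APPLICATION_ID}")
        conn.execute(f"PRAGMA user_version = {SCHEMA_VERSION}")
    conn.execute("PRAGMA foreign_keys = ON")  # executescript resets the txn, not pragmas
    return conn


def connect(path: str | Path) -> sqlite3.Connection:
    """Open an existing study database with referential integrity on."""
    path = Path(path)
    if not path.exists():
        raise SchemaMismatchError(f"{path} does not exist; run init_db first")
    conn = _configure(sqlite3.connect(path))
    if conn.execute("PRAGMA application_id").fetchone()[0] != APPLICATION_ID:
        conn.close()
        raise SchemaMismatchError(f"{path} was not created by this package")
    return conn


def user_tables(conn: sqlite3.Connection) -> list[str]:
    rows = conn.execute(
        "SELECT name FROM sqlite_master WHERE type='table' AND name NOT LIKE 'sqlite_%'"
        " ORDER BY name"
    )
    return [r[0] for r in rows]


def columns(conn: sqlite3.Connection, table: str) -> list[str]:
    return [r[1] for r in conn.execute(f'PRAGMA table_info("{table}")')]


def schema_stats(conn: sqlite3.Connection) -> SchemaStats:
    """Introspect table/column/foreign-key counts from the live catalog."""
    tables = user_tables(conn)
    if not tables:
        raise SchemaMismatchError("database has no tables; not initialized")
    n_fields = 0
    n_rel = 0
    for t in tables:
        n_fields += len(columns(conn, t))
        n_rel += len({r[0] for r in conn.execute(f'PRAGMA foreign_key_list("{t}")')})
    return SchemaStats(n_tables=len(tables), n_fields=n_fields, n_relationships=n_rel)


def integrity_report(conn: sqlite3.Connection) -> IntegrityReport:
    """Name tables missing from, or foreign to, the canonical schema."""
    present = set(user_tables(conn))
    expected = set(canonical_tables())
    return IntegrityReport(
        missing_tables=sorted(expected - present),
        unexpected_tables=sorted(present - expected),
    )


def imaging_tables(conn: sqlite3.Connection) -> list[str]:
    """The tables of the ImagingData group, verified present in *conn*."""
    present = set(user_tables(conn))
    if not present:
        raise SchemaMismatchError("database has no tables; not initialized")
    return [t for t in TABLE_GROUPS["ImagingData"] if t in present]


def get_patient(conn: sqlite3.Connection, patient_code: str) -> sqlite3.Row | None:
    return conn.execute(
        "SELECT * FROM Patients WHERE patient_code = ?", (patient_code,)
    ).fetchone()
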