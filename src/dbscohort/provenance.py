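"""File lineage, spatial-transformation records, and the unified query layer.

Every managed file is one row of ``Files``. A file produced from another file
points back to it through ``source_id``; if the production step was a spatial
transformation, ``transformation_id`` points to a ``Transformations`` row
pairing the warp file (``transform_id``) with the image defining the
destination space (``target_id``). Walking ``source_id`` links from any file
back to its raw original yields its lineage; the write paths keep that graph
acyclic.

The query layer answers the group-analysis question "give me every file of
every ET patient in atlas space v1" in one call, joined with the clinical
attributes needed to filter.
"""

from __future__ import annotations

import shutil
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

from . import bids as _bids
from . import schema as _schema
from .errors import ConflictError, CriteriaError, IntegrityError, NotFoundError


@dataclass(frozen=True)
class FileRecord:
    file_id: int
    path: str
    file_type: str
    category: str | None = None
    patient_id: int | None = None
    electrode_id: int | None = None
    source_id: int | None = None
    transformation_id: int | None = None

    @classmethod
    def from_row(cls, row: sqlite3.Row) -> "FileRecord":
        return cls(**{k: row[k] for k in cls.__dataclass_fields__})


@dataclass(frozen=True)
class TransformationRecord:
    transformation_id: int
    transform_id: int
    target_id: int

    @classmethod
    def from_row(cls, row: sqlite3.Row) -> "TransformationRecord":
        return cls(row["transformation_id"], row["transform_id"], row["target_id"])


@dataclass(frozen=True)
class LineageStep:
    file: FileRecord
    transformation: TransformationRecord | None = None


@dataclass
class QueryCriteria:
    """Conjunctive predicates for file selection; empty criteria match all."""

    disease: str | None = None
    center: str | None = None
    subject_ids: list[str] | None = None
    space: str | None = None
    file_type: str | None = None
    suffix: str | None = None
    session: str | None = None
    category: str | None = None


def _file(db: sqlite3.Connection, file_id: int) -> sqlite3.Row:
    row = db.execute("SELECT * FROM Files WHERE file_id = ?", (file_id,)).fetchone()
    if row is None:
        raise NotFoundError(f"no file with id {file_id}")
    return row


def register_file(
    db: sqlite3.Connection,
    path: str,
    file_type: str,
    category: str | None = None,
    patient_id: int | None = None,
    electrode_id: int | None = None,
    source_id: int | None = None,
    transformation_id: int | None = None,
) -> int:
    """Register a managed file; registering an identical path is a no-op.

    A path collision with different metadata raises :class:`ConflictError`;
    dangling parent links raise :class:`IntegrityError`.
    """
    if file_type not in _bids.FILE_TYPES:
        raise CriteriaError(f"unknown file type {file_type!r}")
    existing = db.execute("SELECT * FROM Files WHERE path = ?", (path,)).fetchone()
    meta = dict(
        patient_id=patient_id,
        electrode_id=electrode_id,
        file_type=file_type,
        category=category,
        source_id=source_id,
        transformation_id=transformation_id,
    )
    if existing is not None:
        diffs = {k: v for k, v in meta.items() if existing[k] != v}
        if diffs:
            raise ConflictError(f"{path}: already registered with different {sorted(diffs)}")
        return existing["file_id"]
    for ref, table, col in (
        (source_id, "Files", "file_id"),
        (transformation_id, "Transformations", "transformation_id"),
        (patient_id, "Patients", "patient_id"),
        (electrode_id, "Electrodes", "electrode_id"),
    ):
        if ref is not None and db.execute(
            f'SELECT 1 FROM "{table}" WHERE "{col}" = ?', (ref,)
        ).fetchone() is None:
            raise IntegrityError(f"dangling {col} = {ref}")
    if transformation_id is not None and source_id is None:
        raise IntegrityError("transformation_id set requires source_id")
    with db:
        cur = db.execute(
            "INSERT INTO Files (patient_id, electrode_id, path, file_type,"
            " category, source_id, transformation_id) VALUES (?,?,?,?,?,?,?)",
            (patient_id, electrode_id, path, file_type, category, source_id, transformation_id),
        )
    return cur.lastrowid


def update_file_source(db: sqlite3.Connection, file_id: int, source_id: int) -> None:
    """Repoint a file's origin, refusing any update that would close a cycle."""
    _file(db, file_id)
    _file(db, source_id)
    if file_id == source_id:
        raise IntegrityError("a file cannot be its own source")
    ancestor: int | None = source_id
    n = db.execute("SELECT count(*) FROM Files").fetchone()[0]
    for _ in range(n + 1):
        if ancestor is None:
            break
        if ancestor == file_id:
            raise IntegrityError(f"setting source_id={source_id} would create a cycle")
        ancestor = _file(db, ancestor)["source_id"]
    with db:
        db.execute("UPDATE Files SET source_id = ? WHERE file_id = ?", (source_id, file_id))


def register_transformation(
    db: sqlite3.Connection, transform_file_id: int, target_file_id: int
) -> int:
    """Pair a warp file with its target-space image; idempotent on the pair."""
    if transform_file_id == target_file_id:
        raise IntegrityError("transform and target must be different files")
    _file(db, transform_file_id)
    _file(db, target_file_id)
    row = db.execute(
        "SELECT transformation_id FROM Transformations WHERE transform_id = ? AND target_id = ?",
        (transform_file_id, target_file_id),
    ).fetchone()
    if row:
        return row[0]
    with db:
        cur = db.execute(
            "INSERT INTO Transformations (transform_id, target_id) VALUES (?, ?)",
            (transform_file_id, target_file_id),
        )
    return cur.lastrowid


def register_derived_image(
    db: sqlite3.Connection,
    root: str | Path,
    source_file_id: int,
    transformation_id: int,
    direction: str,
    payload: str | Path | None = None,
) -> int:
    """Register the output of transforming *source* into another space.

    The output name and category follow the cross-space naming rule; the new
    Files row carries ``source_id`` and ``transformation_id`` and a Bids row
    is created. With *payload* given, the produced image is copied to its
    resolved location (otherwise registration is bookkeeping only and the
    tree validator will flag the missing file until the image is written).
    """
    root = Path(root)
    src = _file(db, source_file_id)
    trow = db.execute(
        "SELECT * FROM Transformations WHERE transformation_id = ?", (transformation_id,)
    ).fetchone()
    if trow is None:
        raise NotFoundError(f"no transformation with id {transformation_id}")
    src_bids = db.execute(
        "SELECT * FROM Bids WHERE file_id = ?", (source_file_id,)
    ).fetchone()
    if src_bids is None:
        raise NotFoundError(f"file {source_file_id} has no Bids row; not an image")
    name = _bids.BidsName(
        subject=src_bids["subject_label"],
        session=src_bids["session_label"],
        acquisition=src_bids["acquisition_label"],
        space=src_bids["space_label"],
        suffix=src_bids["suffix"],
        extension=src_bids["extension"],
    )
    target_bids = db.execute(
        "SELECT * FROM Bids WHERE file_id = ?", (trow["target_id"],)
    ).fetchone()
    if target_bids is None:
        raise NotFoundError("transformation target has no Bids row")

    if direction == _bids.PATIENT_TO_ATLAS:
        target_ref = _bids.SubjectRef(
            "Atlas",
            target_bids["subject_label"],
            atlas_version=target_bids["session_label"] or "unversioned",
        )
        folder_subject = _bids.SubjectRef("Patient", name.subject)
        patient_id = src["patient_id"]
    elif direction == _bids.ATLAS_TO_PATIENT:
        target_ref = _bids.SubjectRef("Patient", target_bids["subject_label"])
        folder_subject = target_ref
        target_file = _file(db, trow["target_id"])
        patient_id = target_file["patient_id"]
    else:
        raise IntegrityError(f"unknown direction {direction!r}")

    new_name, category = _bids.derive_transformed_name(name, target_ref, direction)
    relpath = _bids.resolve_path(new_name, folder_subject, category)
    if payload is not None:
        dest = root / relpath
        dest.parent.mkdir(parents=True, exist_ok=True)
        if not dest.exists():
            shutil.copyfile(payload, dest)

    file_id = register_file(
        db,
        path=str(relpath),
        file_type=_bids.file_type_for(category, new_name.suffix),
        category=category,
        patient_id=patient_id,
        source_id=source_file_id,
        transformation_id=transformation_id,
    )
    with db:
        db.execute(
            "INSERT OR IGNORE INTO Bids (file_id, subject_label, session_label,"
            " acquisition_label, space_label, suffix, extension, modality)"
            " VALUES (?,?,?,?,?,?,?,?)",
            (
                file_id,
                new_name.subject,
                new_name.session,
                new_name.acquisition,
                new_name.space,
                new_name.suffix,
                new_name.extension,
                src_bids["modality"],
            ),
        )
    return file_id


def lineage(db: sqlite3.Connection, file_id: int) -> list[LineageStep]:
    """Ordered chain from the raw original to the queried file.

    Each step carries the transformation that produced its file, if any.
    Terminates because the write paths enforce acyclicity.
    """
    chain: list[LineageStep] = []
    n = db.execute("SELECT count(*) FROM Files").fetchone()[0]
    current: int | None = file_id
    for _ in range(n + 1):
        if current is None:
            break
        row = _file(db, current)
        step_t = None
        if row["transformation_id"] is not None:
            trow = db.execute(
                "SELECT * FROM Transformations WHERE transformation_id = ?",
                (row["transformation_id"],),
            ).fetchone()
            step_t = TransformationRecord.from_row(trow)
        chain.append(LineageStep(FileRecord.from_row(row), step_t))
        current = row["source_id"]
    else:
        raise IntegrityError(f"lineage of file {file_id} does not terminate")
    chain.reverse()
    return chain


def delete_file(db: sqlite3.Connection, file_id: int, cascade: bool = False) -> int:
    """Delete a file row; with registered descendants only when *cascade*.

    Returns the number of rows deleted.
    """
    _file(db, file_id)
    children = [
        r[0] for r in db.execute("SELECT file_id FROM Files WHERE source_id = ?", (file_id,))
    ]
    if children and not cascade:
        raise IntegrityError(
            f"file {file_id} has derived descendants {children}; pass cascade=True"
        )
    deleted = 0
    for child in children:
        deleted += delete_file(db, child, cascade=True)
    with db:
        db.execute("DELETE FROM Labels WHERE file_id = ?", (file_id,))
        db.execute("DELETE FROM Bids WHERE file_id = ?", (file_id,))
        db.execute(
            "DELETE FROM Transformations WHERE transform_id = ? OR target_id = ?",
            (file_id, file_id),
        )
        db.execute("DELETE FROM Files WHERE file_id = ?", (file_id,))
    return deleted + 1


_FULL_JOIN = """
SELECT f.file_id, f.path, f.file_type, f.category, f.patient_id, f.electrode_id,
       f.source_id, f.transformation_id,
       b.subject_label, b.session_label, b.acquisition_label, b.space_label,
       b.suffix, b.extension, b.modality,
       p.patient_code, p.center, p.disease, p.sex, p.age_at_surgery
FROM Files f
LEFT JOIN Bids b ON b.file_id = f.file_id
LEFT JOIN Patients p ON p.patient_id = f.patient_id
"""

#: Fixed column order of query serializations.
QUERY_COLUMNS = (
    "file_id", "path", "file_type", "category", "patient_id", "electrode_id",
    "source_id", "transformation_id", "subject_label", "session_label",
    "acquisition_label", "space_label", "suffix", "extension", "modality",
    "patient_code", "center", "disease", "sex", "age_at_surgery",
)


def select_files(db: sqlite3.Connection, criteria: QueryCriteria | None = None) -> list[dict]:
    """Select files by clinical and imaging predicates in one step.

    Results are the conjunction of all given predicates over the full
    Files ⋈ Bids ⋈ Patients join, ordered by (subject id, path).
    """
    criteria = criteria or QueryCriteria()
    if criteria.disease is not None and criteria.disease not in _schema.DISEASES:
        raise CriteriaError(f"unknown disease {criteria.disease!r}")
    if criteria.file_type is not None and criteria.file_type not in _bids.FILE_TYPES:
        raise CriteriaError(f"unknown file type {criteria.file_type!r}")
    if criteria.category is not None and criteria.category not in _bids.CATEGORIES:
        raise CriteriaError(f"unknown category {criteria.category!r}")

    where, params = [], []
    for clause, value in (
        ("p.disease = ?", criteria.disease),
        ("p.center = ?", criteria.center),
        ("b.space_label = ?", criteria.space),
        ("f.file_type = ?", criteria.file_type),
        ("b.suffix = ?", criteria.suffix),
        ("b.session_label = ?", criteria.session),
        ("f.category = ?", criteria.category),
    ):
        if value is not None:
            where.append(clause)
            params.append(value)
    if criteria.subject_ids is not None:
        marks = ", ".join("?" for _ in criteria.subject_ids)
        where.append(f"coalesce(p.patient_code, b.subject_label) IN ({marks})")
        params.extend(criteria.subject_ids)

    sql = _FULL_JOIN
    if where:
        sql += " WHERE " + " AND ".join(where)
    sql += " ORDER BY coalesce(p.patient_code, b.subject_label, ''), f.path"
    return [dict(r) for r in db.execute(sql, params)]


def patient_bundle(db: sqlite3.Connection, patient_code: str) -> dict:
    """Everything the database holds for one patient, grouped by section."""
    patient = _schema.get_patient(db, patient_code)
    if patient is None:
        raise NotFoundError(f"no patient with code {patient_code!r}")
    pid = patient["patient_id"]
    bundle: dict = {"demographics": dict(patient)}

    direct = {
        "clinical_general": "ClinicalDataGeneral",
        "eval_tremor": "ClinicalEvalTremor",
        "eval_updrs": "ClinicalEvalUpdrs",
        "eval_qol": "ClinicalEvalQol",
        "postop_screenings": "PostopScreenings",
        "imaging_acquisitions": "ImagingAcquisitions",
        "stimulation_sessions": "StimulationSessions",
        "mer_sessions": "MerSessions",
        "targeting": "TargetingPlans",
        "chronic_settings": "ChronicSettings",
        "implanted_positions": "ImplantedPositions",
    }
    for section, table in direct.items():
        bundle[section] = [
            dict(r)
            for r in db.execute(f'SELECT * FROM "{table}" WHERE patient_id = ?', (pid,))
        ]
    bundle["stimulations"] = [
        dict(r)
        for r in db.execute(
            "SELECT s.* FROM Stimulations s JOIN StimulationSessions ss"
            " ON ss.stim_session_id = s.stim_session_id WHERE ss.patient_id = ?",
            (pid,),
        )
    ]
    bundle["files"] = [
        dict(r)
        for r in db.execute(
            "SELECT * FROM Files WHERE patient_id = ? ORDER BY path", (pid,)
        )
    ]
    return bundle
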