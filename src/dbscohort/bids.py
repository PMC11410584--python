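"""DBS-specific BIDS raw + derivatives layout.

Raw anatomical acquisitions live at ``sub-<id>/ses-<ses>/anat/``; everything
produced by analysis lives under ``derivatives/sub-<id>/<Category>/`` where
the category folder names the *content* of the files (``Segmentations``,
``PatientInAtlas``, ``AtlasInPatient``, ``Trajectories``, ``VTA``,
``Conductivity``, ``Transforms``, ``ElectrodeModel``).

Cross-space bookkeeping is encoded in the filename itself: transforming
``sub-<id>_ses-<ses>_acq-<a>_T1w.nii.gz`` into the space of atlas version
``v`` yields ``sub-<id>_space-<v>_ses-<ses>_acq-<a>_T1w.nii.gz`` under
``derivatives/sub-<id>/PatientInAtlas``; the reverse direction stamps the
patient id into the ``space`` entity and files the output under
``AtlasInPatient``. Atlas-space files belong to the reserved subject
``ATLAS`` with the atlas version as their session label; electrode model
files belong to subjects with the reserved ``ELEC`` prefix.

Filenames are emitted with the entity order ``sub, space, ses, acq`` followed
by the suffix; parsing accepts entities in any order.
"""

from __future__ import annotations

import hashlib
import json
import re
import shutil
import sqlite3
from dataclasses import dataclass, replace
from pathlib import Path, PurePosixPath

from . import schema as _schema
from .errors import BidsNameError, ConflictError, LayoutError
from .redcap import IngestReport

BIDS_VERSION = "1.9.0"

EXTENSIONS = (".nii.gz", ".nii", ".json", ".h5", ".txt")

#: Reserved subject-id conventions encoding subject type in the flat
#: derivatives layout.
ATLAS_SUBJECT = "ATLAS"
ELECTRODE_PREFIX = "ELEC"

SUBJECT_TYPES = ("Patient", "Atlas", "Electrode")

#: Content categories. ``anat-raw`` is the only one living outside
#: ``derivatives``.
CATEGORIES = (
    "anat-raw",
    "Segmentations",
    "PatientInAtlas",
    "AtlasInPatient",
    "Trajectories",
    "VTA",
    "Conductivity",
    "Transforms",
    "ElectrodeModel",
)

#: Directions for cross-space derivation.
PATIENT_TO_ATLAS = "PatientToAtlas"
ATLAS_TO_PATIENT = "AtlasToPatient"

#: General file-type vocabulary stored in Files.file_type.
FILE_TYPES = (
    "anat",
    "ct",
    "label",
    "warp",
    "trajectory",
    "vta",
    "conductivity",
    "electrode-model",
    "other",
)

_LABEL_RE = re.compile(r"^[A-Za-z0-9]+$")
_ENTITY_KEYS = ("sub", "space", "ses", "acq")  # emission order


@dataclass(frozen=True)
class BidsName:
    """Parsed entity set of one filename."""

    subject: str
    suffix: str
    extension: str
    session: str | None = None
    acquisition: str | None = None
    space: str | None = None


@dataclass(frozen=True)
class SubjectRef:
    subject_type: str
    subject_id: str
    atlas_version: str | None = None

    def __post_init__(self) -> None:
        if self.subject_type not in SUBJECT_TYPES:
            raise LayoutError(f"unknown subject type {self.subject_type!r}")
        if (self.subject_type == "Atlas") != (self.atlas_version is not None):
            raise LayoutError("atlas_version present iff subject_type is Atlas")


@dataclass(frozen=True)
class TreeViolation:
    path: str
    rule: str
    severity: str = "error"  # or "warning"


def _check_label(label: str, what: str) -> None:
    if not _LABEL_RE.fullmatch(label):
        raise BidsNameError(
            f"{what} label {label!r} must be alphanumeric (no underscore or hyphen)"
        )


def split_extension(filename: str) -> tuple[str, str]:
    for ext in EXTENSIONS:  # .nii.gz before .nii
        if filename.endswith(ext):
            return filename[: -len(ext)], ext
    raise BidsNameError(f"{filename!r}: unknown extension")


def parse_bids_name(filename: str) -> BidsName:
    """Parse a filename into its entity set, tolerating any entity order."""
    stem, ext = split_extension(filename)
    tokens = stem.split("_")
    if len(tokens) < 2:
        raise BidsNameError(f"{filename!r}: need at least a sub- entity and a suffix")
    suffix = tokens[-1]
    _check_label(suffix, "suffix")
    entities: dict[str, str] = {}
    unknown = []
    for tok in tokens[:-1]:
        if "-" not in tok:
            raise BidsNameError(f"{filename!r}: malformed entity token {tok!r}")
        key, _, label = tok.partition("-")
        if key not in _ENTITY_KEYS:
            unknown.append(key)
            continue
        if key in entities:
            raise BidsNameError(f"{filename!r}: repeated entity {key!r}")
        _check_label(label, key)
        entities[key] = label
    if unknown:
        raise BidsNameError(f"{filename!r}: unknown entity keys {unknown}")
    if "sub" not in entities:
        raise BidsNameError(f"{filename!r}: missing sub- entity")
    return BidsName(
        subject=entities["sub"],
        space=entities.get("space"),
        session=entities.get("ses"),
        acquisition=entities.get("acq"),
        suffix=suffix,
        extension=ext,
    )


def format_bids_name(name: BidsName) -> str:
    """Emit the filename with fixed entity order sub, space, ses, acq."""
    _check_label(name.subject, "subject")
    _check_label(name.suffix, "suffix")
    if name.extension not in EXTENSIONS:
        raise BidsNameError(f"unknown extension {name.extension!r}")
    parts = [f"sub-{name.subject}"]
    for key, value in (
        ("space", name.space),
        ("ses", name.session),
        ("acq", name.acquisition),
    ):
        if value is not None:
            _check_label(value, key)
            parts.append(f"{key}-{value}")
    parts.append(name.suffix)
    return "_".join(parts) + name.extension


def derive_transformed_name(
    source: BidsName, target: SubjectRef, direction: str
) -> tuple[BidsName, str]:
    """Name and categorise the output of a cross-space transformation.

    The source must be in its native space (no ``space`` entity); all its
    entities are preserved except ``space``, which receives the destination
    space label.
    """
    if source.space is not None:
        raise LayoutError(
            f"source already carries space-{source.space}; it is not in native space"
        )
    if direction == PATIENT_TO_ATLAS:
        if target.subject_type != "Atlas":
            raise LayoutError("PatientToAtlas requires an Atlas target")
        return replace(source, space=target.atlas_version), "PatientInAtlas"
    if direction == ATLAS_TO_PATIENT:
        if target.subject_type != "Patient":
            raise LayoutError("AtlasToPatient requires a Patient target")
        return replace(source, space=target.subject_id), "AtlasInPatient"
    raise LayoutError(f"unknown direction {direction!r}")


def resolve_path(name: BidsName, subject: SubjectRef, category: str) -> PurePosixPath:
    """Relative location of a file in the tree; a pure function of its inputs.

    Raw anatomical images: ``sub-<id>/ses-<ses>/anat/<filename>``. All
    derivatives: ``derivatives/sub-<id>/<Category>/<filename>``, where the
    folder subject is the patient for the cross-space categories (the
    filename may then carry the ATLAS subject, as for atlas structures
    projected into a patient space).
    """
    if category not in CATEGORIES:
        raise LayoutError(f"unknown category {category!r}")
    st = subject.subject_type
    if category == "anat-raw":
        if st != "Patient":
            raise LayoutError("raw anatomical images belong to Patient subjects")
        if name.session is None:
            raise LayoutError("raw anatomical images need a session")
        if name.space is not None:
            raise LayoutError("raw anatomical images are in native space")
        return PurePosixPath(
            f"sub-{subject.subject_id}", f"ses-{name.session}", "anat",
            format_bids_name(name),
        )
    if category == "ElectrodeModel":
        if st != "Electrode":
            raise LayoutError("ElectrodeModel files belong to Electrode subjects")
    elif st == "Electrode":
        raise LayoutError(f"Electrode subjects only hold ElectrodeModel files, not {category}")
    if category in ("PatientInAtlas", "AtlasInPatient") and st != "Patient":
        raise LayoutError(f"{category} files are filed under the patient subject")
    return PurePosixPath(
        "derivatives", f"sub-{subject.subject_id}", category, format_bids_name(name)
    )


def subject_ref_for(subject_id: str, session: str | None = None) -> SubjectRef:
    """Infer the subject type from the reserved id conventions."""
    if subject_id == ATLAS_SUBJECT:
        return SubjectRef("Atlas", subject_id, atlas_version=session or "unversioned")
    if subject_id.startswith(ELECTRODE_PREFIX):
        return SubjectRef("Electrode", subject_id)
    return SubjectRef("Patient", subject_id)


def file_type_for(category: str, suffix: str) -> str:
    if category == "anat-raw":
        return "ct" if suffix.upper() == "CT" else "anat"
    if suffix in ("dseg", "mask"):
        return "label"
    return {
        "Segmentations": "label",
        "Transforms": "warp",
        "Trajectories": "trajectory",
        "VTA": "vta",
        "Conductivity": "conductivity",
        "ElectrodeModel": "electrode-model",
    }.get(category, "other")


# --- image ingestion -------------------------------------------------------

_MANIFEST_REQUIRED = ("source_path", "subject", "subject_type", "suffix", "category")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def read_manifest(path: str | Path) -> list[dict]:
    """Read an image manifest (CSV or JSON list of objects)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        entries = json.loads(path.read_text())
    else:
        import csv

        with path.open(newline="", encoding="utf-8") as fh:
            entries = list(csv.DictReader(fh))
    return entries


def scan_tree(directory: str | Path) -> list[dict]:
    """Build manifest entries from a directory of images with JSON sidecars.

    Each image's sidecar must carry the same keys a manifest row would.
    """
    directory = Path(directory)
    entries = []
    for img in sorted(directory.rglob("*")):
        if not img.is_file() or img.suffix == ".json":
            continue
        try:
            stem, _ = split_extension(img.name)
        except BidsNameError:
            continue
        sidecar = img.parent / (stem + ".json")
        if not sidecar.exists():
            continue
        meta = json.loads(sidecar.read_text())
        entry = {k: meta.get(k, "") for k in _MANIFEST_REQUIRED}
        entry.update(
            {
                k: meta.get(k, "")
                for k in ("session", "acquisition", "space", "structure_label", "modality")
            }
        )
        entry["source_path"] = str(img)
        entries.append(entry)
    return entries


def write_dataset_descriptions(root: Path) -> None:
    for where, dtype in ((root, "raw"), (root / "derivatives", "derivative")):
        where.mkdir(parents=True, exist_ok=True)
        desc = where / "dataset_description.json"
        if not desc.exists():
            payload = {
                "Name": "DBS cohort imaging data",
                "BIDSVersion": BIDS_VERSION,
                "DatasetType": dtype,
            }
            if dtype == "derivative":
                payload["GeneratedBy"] = [{"Name": "dbscohort"}]
            desc.write_text(json.dumps(payload, indent=2) + "\n")


def ingest_images(
    source: str | Path | list[dict],
    db: sqlite3.Connection,
    root: str | Path,
) -> IngestReport:
    """Copy images into the tree and register them in the database.

    *source* is a manifest path (CSV/JSON), a directory to scan, or an
    already-loaded list of manifest entries. Every file gets a Files row; every
    image a Bids row; every labeled-structure file a Labels row. Electrode
    model files additionally maintain the electrode catalog (Electrodes +
    ElectrodeContactGeometry) from their sidecar metadata. Re-ingestion of
    identical input adds zero rows; a path collision with different content is
    an error.
    """
    from . import provenance as _prov

    root = Path(root)
    if isinstance(source, (str, Path)):
        src = Path(source)
        entries = scan_tree(src) if src.is_dir() else read_manifest(src)
        base = src.parent if src.is_file() else Path(".")
    else:
        entries, base = source, Path(".")

    write_dataset_descriptions(root)
    report = IngestReport()

    def sort_key(e: dict) -> tuple:
        return tuple(str(e.get(k, "")) for k in ("subject", "session", "suffix", "source_path"))

    with db:
        for entry in sorted(entries, key=sort_key):
            _ingest_one(entry, base, db, root, report, _prov)
    return report


def _ingest_one(entry, base, db, root, report, _prov):
    ident = str(entry.get("source_path", "?"))
    missing = [k for k in _MANIFEST_REQUIRED if not (entry.get(k) or "").strip()]
    if missing:
        report.reject(ident, ",".join(missing), "missing manifest fields")
        return
    src = Path(entry["source_path"])
    if not src.is_absolute():
        src = base / src
    if not src.exists():
        report.reject(ident, "source_path", "source file does not exist")
        return
    if entry["subject_type"] not in SUBJECT_TYPES:
        report.reject(ident, "subject_type", f"unknown subject type {entry['subject_type']!r}")
        return

    def opt(k):
        v = (entry.get(k) or "").strip()
        return v or None

    try:
        _, ext = split_extension(src.name)
        name = BidsName(
            subject=entry["subject"].strip(),
            session=opt("session"),
            acquisition=opt("acquisition"),
            space=opt("space"),
            suffix=entry["suffix"].strip(),
            extension=opt("extension") or ext,
        )
        if entry["subject_type"] == "Atlas":
            subject = SubjectRef("Atlas", name.subject, atlas_version=name.session or "unversioned")
        else:
            subject = SubjectRef(entry["subject_type"], name.subject)
        relpath = resolve_path(name, subject, entry["category"])
    except (BidsNameError, LayoutError) as exc:
        report.reject(ident, "", str(exc))
        return

    patient_id = electrode_id = None
    if subject.subject_type == "Patient":
        patient = _schema.get_patient(db, subject.subject_id)
        if patient is None:
            report.reject(ident, "subject", f"unknown patient {subject.subject_id!r}")
            return
        patient_id = patient["patient_id"]
    elif subject.subject_type == "Electrode":
        electrode_id = _ensure_electrode(db, subject.subject_id, src)

    dest = root / relpath
    if dest.exists():
        if _sha256(dest) != _sha256(src):
            raise ConflictError(f"{relpath}: exists with different content")
        new_file = False
    else:
        dest.parent.mkdir(parents=True, exist_ok=True)
        shutil.copyfile(src, dest)
        new_file = True
    sidecar_src = src.parent / (split_extension(src.name)[0] + ".json")
    meta = json.loads(sidecar_src.read_text()) if sidecar_src.exists() else {}
    if sidecar_src.exists() and name.extension != ".json":
        sc_name = replace(name, extension=".json")
        sc_dest = dest.parent / format_bids_name(sc_name)
        if not sc_dest.exists():
            shutil.copyfile(sidecar_src, sc_dest)

    existing = db.execute(
        "SELECT file_id FROM Files WHERE path = ?", (str(relpath),)
    ).fetchone()
    file_type = file_type_for(entry["category"], name.suffix)
    file_id = _prov.register_file(
        db,
        path=str(relpath),
        file_type=file_type,
        category=entry["category"],
        patient_id=patient_id,
        electrode_id=electrode_id,
    )
    inserted = existing is None
    if inserted:
        db.execute(
            "INSERT OR IGNORE INTO Bids (file_id, subject_label, session_label,"
            " acquisition_label, space_label, suffix, extension, modality,"
            " acquisition_time, echo_time_ms, repetition_time_ms)"
            " VALUES (?,?,?,?,?,?,?,?,?,?,?)",
            (
                file_id,
                name.subject,
                name.session,
                name.acquisition,
                name.space,
                name.suffix,
                name.extension,
                opt("modality") or meta.get("Modality"),
                meta.get("AcquisitionTime"),
                meta.get("EchoTime"),
                meta.get("RepetitionTime"),
            ),
        )
        if opt("structure_label"):
            db.execute(
                "INSERT OR IGNORE INTO Labels (file_id, structure_name, hemisphere,"
                " label_value, annotator) VALUES (?,?,?,?,?)",
                (
                    file_id,
                    opt("structure_label"),
                    opt("hemisphere"),
                    meta.get("LabelValue"),
                    meta.get("Annotator"),
                ),
            )
        if subject.subject_type == "Electrode":
            db.execute(
                "UPDATE Electrodes SET model_file_id = ? WHERE electrode_id = ?",
                (file_id, electrode_id),
            )
            _fill_electrode_geometry(db, electrode_id, meta)
        report.inserted += 1
    elif new_file:
        report.updated += 1


def _ensure_electrode(db: sqlite3.Connection, subject_id: str, src: Path) -> int:
    model = subject_id[len(ELECTRODE_PREFIX):] or subject_id
    row = db.execute(
        "SELECT electrode_id FROM Electrodes WHERE model_name = ?", (model,)
    ).fetchone()
    if row:
        return row[0]
    sidecar = src.parent / (split_extension(src.name)[0] + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    cur = db.execute(
        "INSERT INTO Electrodes (model_name, manufacturer, n_contacts,"
        " lead_diameter_mm, span_mm, material) VALUES (?,?,?,?,?,?)",
        (
            model,
            meta.get("Manufacturer"),
            meta.get("NContacts"),
            meta.get("LeadDiameterMm"),
            meta.get("SpanMm"),
            meta.get("Material"),
        ),
    )
    return cur.lastrowid


def _fill_electrode_geometry(db: sqlite3.Connection, electrode_id: int, meta: dict) -> None:
    n = meta.get("NContacts")
    if not n:
        return
    have = db.execute(
        "SELECT count(*) FROM ElectrodeContactGeometry WHERE electrode_id = ?",
        (electrode_id,),
    ).fetchone()[0]
    if have:
        return
    for i in range(int(n)):
        db.execute(
            "INSERT INTO ElectrodeContactGeometry (electrode_id, contact_index,"
            " contact_label, contact_length_mm, spacing_mm) VALUES (?,?,?,?,?)",
            (electrode_id, i, f"C{i}", meta.get("ContactLengthMm"), meta.get("SpacingMm")),
        )


# --- tree validation -------------------------------------------------------


def validate_tree(root: str | Path, db: sqlite3.Connection) -> list[TreeViolation]:
    """Lint the tree against the layout rules and the database.

    Violations are data, not exceptions: every filename must parse, lie at
    its resolved location, and have a database row; every database path must
    exist on disk; dataset_description.json must be present at the root and
    in derivatives.
    """
    root = Path(root)
    violations: list[TreeViolation] = []

    for where in (root, root / "derivatives"):
        if not (where / "dataset_description.json").exists():
            violations.append(
                TreeViolation(str(where / "dataset_description.json"), "missing dataset_description.json")
            )

    db_paths = {r[0] for r in db.execute("SELECT path FROM Files")}
    on_disk: set[str] = set()

    for f in sorted(root.rglob("*")):
        if not f.is_file():
            continue
        rel = f.relative_to(root).as_posix()
        if f.name == "dataset_description.json":
            continue
        try:
            name = parse_bids_name(f.name)
        except BidsNameError as exc:
            violations.append(TreeViolation(rel, f"unparseable name: {exc}"))
            continue
        subject, category = _infer_location(f.relative_to(root))
        if subject is None:
            violations.append(TreeViolation(rel, f"file outside any recognised folder"))
            continue
        try:
            expected = resolve_path(name, subject, category)
        except LayoutError as exc:
            violations.append(TreeViolation(rel, f"layout rule: {exc}"))
            continue
        if name.extension == ".json":
            continue  # sidecar: located with its image, no database row
        if expected.as_posix() != rel:
            violations.append(
                TreeViolation(rel, f"misplaced: expected {expected.as_posix()}")
            )
            continue
        on_disk.add(rel)
        if rel not in db_paths:
            violations.append(TreeViolation(rel, "no database row for on-disk file"))

    for path in sorted(db_paths):
        if not (root / path).exists():
            violations.append(
                TreeViolation(path, "database row references a missing file")
            )
    return violations


def _infer_location(rel: Path) -> tuple[SubjectRef | None, str | None]:
    parts = rel.parts
    try:
        if parts[0] == "derivatives" and len(parts) == 4:
            sub = parts[1]
            if not sub.startswith("sub-"):
                return None, None
            name = parse_bids_name(parts[3])
            return subject_ref_for(sub[4:], name.session), parts[2]
        if len(parts) == 4 and parts[1].startswith("ses-") and parts[2] == "anat":
            if not parts[0].startswith("sub-"):
                return None, None
            return SubjectRef("Patient", parts[0][4:]), "anat-raw"
    except (BidsNameError, LayoutError):
        return None, None
    return None, None
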