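"""Clinical CSV export parsing, cleaning rules, and transactional ingestion."""

import csv

import pytest
import yaml

from dbscohort import errors, fixtures, redcap, schema


@pytest.fixture()
def db(tmp_path):
    conn = schema.init_db(tmp_path / "s.db")
    yield conn
    conn.close()


# --- clean_value -----------------------------------------------------------

identity = redcap.CleaningRule()


@pytest.mark.parametrize(
    "raw,rule,validation,expected",
    [
        ("12,5", redcap.CleaningRule(kind="decimal-normalize"), {"type": "number"}, 12.5),
        ("  42 ", identity, {"type": "integer"}, 42),
        ("15.03.2022", redcap.CleaningRule(kind="date-normalize"), {"type": "date"}, "2022-03-15"),
        ("2022-03-15", redcap.CleaningRule(kind="date-normalize"), {"type": "date"}, "2022-03-15"),
        ("1", redcap.CleaningRule(kind="code-to-label", codes={"1": "ET", "2": "PD"}),
         {"choices": ["ET", "PD"]}, "ET"),
        ("a  b", redcap.CleaningRule(kind="regex-substitute", pattern=r"\s+", replacement=" "),
         {}, "a b"),
    ],
)
def test_clean_value_accepts(raw, rule, validation, expected):
    value, err = redcap.clean_value(raw, rule, validation)
    assert err is None
    assert value == expected


@pytest.mark.parametrize(
    "raw,rule,validation,fragment",
    [
        ("abc", identity, {"type": "number", "min": -100, "max": 100}, "not numeric"),
        ("150", identity, {"type": "number", "min": -100, "max": 100}, "above maximum"),
        ("-150", identity, {"type": "number", "min": -100, "max": 100}, "below minimum"),
        ("3", redcap.CleaningRule(kind="code-to-label", codes={"1": "ET"}), {}, "unknown code"),
        ("31.02.x", redcap.CleaningRule(kind="date-normalize"), {}, "not a date"),
        ("XX", identity, {"choices": ["ET", "PD"]}, "not in"),
    ],
)
def test_clean_value_rejects_with_reason(raw, rule, validation, fragment):
    value, err = redcap.clean_value(raw, rule, validation)
    assert value is None
    assert fragment in err


def test_empty_cell_is_missing_not_rejected():
    assert redcap.clean_value("", identity, {"type": "number"}) == (None, None)
    assert redcap.clean_value("   ", identity, {}) == (None, None)


def test_bad_cleaning_rules_fail_construction():
    with pytest.raises(errors.MappingError):
        redcap.CleaningRule(kind="frobnicate")
    with pytest.raises(Exception):
        redcap.CleaningRule(kind="regex-substitute", pattern="(unclosed")
    with pytest.raises(errors.MappingError):
        # not injective
        redcap.CleaningRule(kind="code-to-label", codes={"1": "ET", "2": "ET"})


# --- mapping files ---------------------------------------------------------


def _write_mapping(path, doc):
    path.write_text(yaml.safe_dump(doc))
    return path


def test_load_mapping_roundtrips_an_entry(tmp_path, db):
    doc = {
        "instruments": ["targeting_plan"],
        "entries": [
            {
                "instrument": "targeting_plan",
                "field": "planned_x",
                "table": "TargetingPlans",
                "column": "x_mm",
                "clean": {"kind": "decimal-normalize"},
                "validate": {"type": "number", "min": -100, "max": 100},
                "required": True,
            }
        ],
    }
    spec = redcap.load_mapping(_write_mapping(tmp_path / "m.yaml", doc), db)
    (entry,) = spec.entries
    assert entry.table == "TargetingPlans" and entry.column == "x_mm"
    assert entry.clean.kind == "decimal-normalize" and entry.required


@pytest.mark.parametrize(
    "doc,fragment",
    [
        ({"instruments": ["i"], "entries": [
            {"instrument": "i", "field": "f", "table": "Foo", "column": "c"}]}, "Foo"),
        ({"instruments": ["i"], "entries": [
            {"instrument": "i", "field": "f", "table": "Patients", "column": "nope"}]}, "nope"),
        ({"instruments": ["i"], "entries": [
            {"instrument": "other", "field": "f", "table": "Patients", "column": "sex"}]},
         "not in the registry"),
        ({"instruments": ["i"], "entries": [
            {"instrument": "i", "field": "f", "table": "Patients", "column": "sex"},
            {"instrument": "i", "field": "f", "table": "Patients", "column": "center"}]},
         "duplicate source"),
    ],
)
def test_load_mapping_rejects_bad_specs(tmp_path, db, doc, fragment):
    with pytest.raises(errors.MappingError, match=fragment):
        redcap.load_mapping(_write_mapping(tmp_path / "m.yaml", doc), db)


def test_empty_mapping_is_valid_and_ingest_is_noop(tmp_path, db):
    spec = redcap.load_mapping(
        _write_mapping(tmp_path / "m.yaml", {"instruments": [], "entries": []}), db
    )
    report = redcap.ingest(redcap.RecordSet(rows={}, columns=[]), spec, db)
    assert (report.inserted, report.updated, report.rejected) == (0, 0, 0)


# --- export parsing --------------------------------------------------------


def test_parse_longitudinal_export(tmp_path):
    csv_path = tmp_path / "e.csv"
    csv_path.write_text(
        "record_id,redcap_event_name,redcap_repeat_instrument,redcap_repeat_instance,a,b,c\n"
        "P1,preop_arm_1,forms,1,1,2,3\n"
        "P2,preop_arm_1,forms,1,4,5,6\n"
    )
    rs = redcap.parse_redcap_export(csv_path)
    assert len(rs) == 2
    assert rs.rows[("P1", "preop_arm_1", "forms", "1")]["b"] == "2"


def test_parse_tolerates_classic_non_repeating_export(tmp_path):
    csv_path = tmp_path / "e.csv"
    csv_path.write_text("record_id,a\nP1,1\n")
    rs = redcap.parse_redcap_export(csv_path)
    assert ("P1", "", "", "") in rs.rows


def test_parse_header_only_export_is_empty(tmp_path):
    csv_path = tmp_path / "e.csv"
    csv_path.write_text("record_id,redcap_event_name,a\n")
    assert len(redcap.parse_redcap_export(csv_path)) == 0


def test_parse_errors(tmp_path):
    no_id = tmp_path / "noid.csv"
    no_id.write_text("patient,a\nP1,1\n")
    with pytest.raises(errors.FormatError, match="record_id"):
        redcap.parse_redcap_export(no_id)

    dup = tmp_path / "dup.csv"
    dup.write_text("record_id,a\nP1,1\nP1,2\n")
    with pytest.raises(errors.FormatError, match="duplicate key"):
        redcap.parse_redcap_export(dup)


# --- ingestion -------------------------------------------------------------


def _ingest_cohort(cohort, db):
    records = redcap.parse_redcap_export(cohort["export_csv"])
    mapping = redcap.load_mapping(cohort["mapping"], db)
    return records, mapping, redcap.ingest(records, mapping, db)


def test_fixture_cohort_ingests_cleanly_and_idempotently(cohort, db):
    records, mapping, report = _ingest_cohort(cohort, db)
    assert report.rejected == 0 and report.inserted > 0
    counts = {
        t: db.execute(f'SELECT count(*) FROM "{t}"').fetchone()[0]
        for t in schema.user_tables(db)
    }
    again = redcap.ingest(records, mapping, db)
    assert (again.inserted, again.updated, again.rejected) == (0, 0, 0)
    counts_after = {
        t: db.execute(f'SELECT count(*) FROM "{t}"').fetchone()[0]
        for t in schema.user_tables(db)
    }
    assert counts_after == counts


def test_bad_coordinate_rejects_one_row_others_ingest(cohort, db, tmp_path):
    bad = fixtures.corrupt(cohort["export_csv"], "bad-coordinate", tmp_path / "bad.csv")
    records = redcap.parse_redcap_export(bad)
    mapping = redcap.load_mapping(cohort["mapping"], db)
    report = redcap.ingest(records, mapping, db)
    # the bad targeting row and its two dependent child rows are rejected
    target_rejects = [r for r in report.rejections if r[2] == "not numeric"]
    assert len(target_rejects) == 1
    n_plans = db.execute("SELECT count(*) FROM TargetingPlans").fetchone()[0]
    assert n_plans == 3 * 2 - 1  # three patients, two hemispheres, one bad row
    assert db.execute("SELECT count(*) FROM Patients").fetchone()[0] == 3


def test_child_rows_of_rejected_parent_are_not_orphaned(cohort, db, tmp_path):
    bad = fixtures.corrupt(cohort["export_csv"], "bad-coordinate", tmp_path / "bad.csv")
    records = redcap.parse_redcap_export(bad)
    mapping = redcap.load_mapping(cohort["mapping"], db)
    redcap.ingest(records, mapping, db)
    # conservation: every ArcSettings row has a living parent
    orphans = db.execute(
        "SELECT count(*) FROM ArcSettings a LEFT JOIN TargetingPlans t"
        " ON t.targeting_id = a.targeting_id WHERE t.targeting_id IS NULL"
    ).fetchone()[0]
    assert orphans == 0
    assert db.execute("SELECT count(*) FROM ArcSettings").fetchone()[0] == 5


def test_structural_mapping_error_aborts_without_writes(cohort, db):
    records = redcap.parse_redcap_export(cohort["export_csv"])
    mapping = redcap.load_mapping(cohort["mapping"], db)
    db.execute("PRAGMA foreign_keys = OFF")
    db.execute("ALTER TABLE ArcSettings DROP COLUMN frame_type")
    with pytest.raises(errors.MappingError):
        redcap.ingest(records, mapping, db)
    assert db.execute("SELECT count(*) FROM Patients").fetchone()[0] == 0


def test_identity_mapping_matches_brute_force_csv_read(tmp_path, db):
    """Oracle: with identity cleaning, ingested cells equal the raw CSV cells."""
    csv_path = tmp_path / "e.csv"
    rows = [("R1", "alpha", "note one"), ("R2", "beta", "note two")]
    with csv_path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "redcap_event_name", "redcap_repeat_instrument",
                    "redcap_repeat_instance", "f_center", "f_hist"])
        for rid, center, hist in rows:
            w.writerow([rid, "baseline", "patient_information", "1", center, hist])
    doc = {
        "instruments": ["patient_information"],
        "entries": [
            {"instrument": "patient_information", "field": "f_center",
             "table": "Patients", "column": "center"},
            {"instrument": "patient_information", "field": "f_hist",
             "table": "Patients", "column": "medical_history"},
        ],
    }
    mapping = redcap.load_mapping(_write_mapping(tmp_path / "m.yaml", doc), db)
    # Patients.disease is NOT NULL; route it too so rows satisfy the schema
    doc["entries"].append(
        {"instrument": "patient_information", "field": "f_center",
         "table": "Patients", "column": "disease"})
    report = redcap.ingest(redcap.parse_redcap_export(csv_path), mapping, db)
    assert report.rejected == len(rows)  # disease missing -> NOT NULL rejection
    # now with disease supplied via a constant-free second column
    db2 = schema.init_db(tmp_path / "s2.db")
    with csv_path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "redcap_event_name", "redcap_repeat_instrument",
                    "redcap_repeat_instance", "f_center", "f_hist", "f_disease"])
        for rid, center, hist in rows:
            w.writerow([rid, "baseline", "patient_information", "1", center, hist, "ET"])
    doc["entries"][-1]["field"] = "f_disease"
    mapping = redcap.load_mapping(_write_mapping(tmp_path / "m.yaml", doc), db2)
    report = redcap.ingest(redcap.parse_redcap_export(csv_path), mapping, db2)
    assert report.rejected == 0
    stored = {
        r["patient_code"]: (r["center"], r["medical_history"])
        for r in db2.execute("SELECT * FROM Patients")
    }
    assert stored == {rid: (center, hist) for rid, center, hist in rows}
    db2.close()


def test_multi_instrument_non_repeating_row(tmp_path, db):
    """A classic row carrying fields of two instruments feeds both tables."""
    csv_path = tmp_path / "e.csv"
    csv_path.write_text(
        "record_id,pi_disease,pi_center,scr_status\n"
        "P9,ET,Basel,improved\n"
    )
    doc = {
        "instruments": ["patient_information", "postop_screening"],
        "entries": [
            {"instrument": "patient_information", "field": "pi_disease",
             "table": "Patients", "column": "disease"},
            {"instrument": "patient_information", "field": "pi_center",
             "table": "Patients", "column": "center"},
            {"instrument": "postop_screening", "field": "scr_status",
             "table": "PostopScreenings", "column": "symptom_status"},
        ],
    }
    mapping = redcap.load_mapping(_write_mapping(tmp_path / "m.yaml", doc), db)
    report = redcap.ingest(redcap.parse_redcap_export(csv_path), mapping, db)
    assert report.rejected == 0
    assert db.execute("SELECT count(*) FROM Patients").fetchone()[0] == 1
    assert db.execute("SELECT count(*) FROM PostopScreenings").fetchone()[0] == 1
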