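"""Seeded synthetic DBS cohort generator.

Emulates what a two-center essential-tremor / Parkinson's cohort produces:
a longitudinal REDCap-style CSV export in which every patient completes ten
distinct instruments (patient information, pre-/post-operative clinical
evaluations, medications, imaging metadata, targeting plan, microelectrode-
recording summaries, stimulation-test evaluations, implanted position,
post-operative screening), the mapping file routing it into the schema, and
an image manifest with minimal valid NIfTI volumes plus JSON sidecars
(pre/post CT and MRI, one STN label, one warp per patient, a shared
atlas-space segmentation and an electrode model file).

Values are drawn uniformly within clinically plausible ranges — the fixtures
exercise plumbing, not epidemiology. Identical (config, seed) runs are
byte-identical; record ids embed the seed so different seeds never collide.
"""

from __future__ import annotations

import csv
import json
import random
import shutil
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import bids as _bids
from . import provenance as _prov
from . import redcap as _redcap
from . import schema as _schema
from .errors import DbsCohortError

INSTRUMENTS = (
    "patient_information",
    "preop_evaluation",
    "postop_evaluation",
    "medications",
    "imaging_metadata",
    "targeting_plan",
    "mer_summary",
    "stimulation_test",
    "implanted_position",
    "postop_screening",
)

CORRUPT_MODES = ("bad-coordinate", "missing-column", "bad-filename", "duplicate-key")


@dataclass
class CohortConfig:
    n_patients: int = 5
    seed: int = 42
    centers: tuple[str, ...] = ("BSL", "CFD")
    disease_weights: dict[str, float] = field(default_factory=lambda: {"ET": 0.5, "PD": 0.5})
    sessions: tuple[str, ...] = ("pre", "post")

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise DbsCohortError("n_patients must be >= 0")
        if abs(sum(self.disease_weights.values()) - 1.0) > 1e-9:
            raise DbsCohortError("disease weights must sum to 1")


def _patient_code(config: CohortConfig, i: int) -> str:
    center = config.centers[i % len(config.centers)]
    return f"{center}S{config.seed}P{i:02d}"


def _num(rng: random.Random, lo: float, hi: float, comma: bool = False) -> str:
    v = round(rng.uniform(lo, hi), 1)
    s = f"{v:.1f}"
    return s.replace(".", ",") if comma else s


def _rows_for_patient(
    rng: random.Random, code: str, center_idx: int, disease: str = "ET"
) -> list[dict]:
    """All export rows of one patient; every instrument marked repeating."""
    rows = []

    def add(instrument, event, instance, fields):
        rows.append(
            {
                "record_id": code,
                "redcap_event_name": event,
                "redcap_repeat_instrument": instrument,
                "redcap_repeat_instance": str(instance),
                **fields,
            }
        )

    disease_code = {"ET": "1", "PD": "2"}.get(disease, "1")
    surgery = f"{rng.randint(1, 28):02d}.{rng.randint(1, 12):02d}.2022"
    add("patient_information", "baseline_arm_1", 1, {
        "pi_center": str(center_idx + 1),
        "pi_disease": disease_code,
        "pi_sex": rng.choice(["0", "1"]),
        "pi_age": _num(rng, 45, 80, comma=True),
        "pi_surgery_date": surgery,
        "pi_handedness": rng.choice(["left", "right"]),
        "pi_diag_year": str(rng.randint(2005, 2020)),
        "pi_history": rng.choice(["unremarkable", "hypertension", "diabetes type 2"]),
    })
    add("preop_evaluation", "preop_arm_1", 1, {
        "pre_eval_date": "01.02.2022",
        "pre_scale": "FTM" if disease_code == "1" else "UPDRS",
        "pre_tremor": _num(rng, 2, 4),
        "pre_handwriting": _num(rng, 1, 4),
        "pre_spiral": _num(rng, 1, 4),
        "pre_updrs_total": _num(rng, 20, 60),
        "pre_rigidity": _num(rng, 0, 4),
        "pre_brady": _num(rng, 0, 4),
        "pre_axial": _num(rng, 0, 4),
        "pre_med_state": rng.choice(["on", "off"]),
    })
    add("postop_evaluation", "postop_arm_1", 1, {
        "post_eval_date": "01.09.2022",
        "post_scale": "FTM" if disease_code == "1" else "UPDRS",
        "post_tremor": _num(rng, 0, 2),
        "post_handwriting": _num(rng, 0, 2),
        "post_spiral": _num(rng, 0, 2),
        "post_updrs_total": _num(rng, 5, 30),
        "post_rigidity": _num(rng, 0, 2),
        "post_brady": _num(rng, 0, 2),
        "post_axial": _num(rng, 0, 2),
        "post_med_state": rng.choice(["on", "off"]),
        "post_qol_instrument": "PDQ-39" if disease_code == "2" else "QUEST",
        "post_qol_total": _num(rng, 10, 60),
        "post_qol_mobility": _num(rng, 0, 100),
        "post_qol_adl": _num(rng, 0, 100),
    })
    for k in range(2):
        add("medications", "baseline_arm_1", k + 1, {
            "med_visit_date": "15.01.2022",
            "med_visit_type": "baseline",
            "med_name": rng.choice(["levodopa", "propranolol", "primidone", "ropinirole"]),
            "med_dose": _num(rng, 25, 400, comma=True),
            "med_freq": str(rng.randint(1, 4)),
            "med_route": "oral",
            "med_start": "01.01.2021",
            "med_ongoing": "1",
        })
    for k, (modality, session) in enumerate((("MRI", "pre"), ("CT", "pre"), ("CT", "post"))):
        add("imaging_metadata", "preop_arm_1", k + 1, {
            "im_modality": modality,
            "im_session": session,
            "im_date": "10.01.2022" if session == "pre" else "20.03.2022",
            "im_scanner": rng.choice(["Siemens Prisma", "GE Discovery", "Philips Ingenia"]),
            "im_field": "3,0" if modality == "MRI" else "",
            "im_slices": str(rng.randint(120, 240)),
            "im_available": "1",
        })
    for k, side in enumerate(("left", "right")):
        add("targeting_plan", "surgery_arm_1", k + 1, {
            "tp_structure": "VIM" if disease_code == "1" else "STN",
            "tp_side": side,
            "tp_x": _num(rng, -15, 15, comma=True),
            "tp_y": _num(rng, -10, 5, comma=True),
            "tp_z": _num(rng, -12, 0, comma=True),
            "tp_acpc": "1",
            "tp_imaging_ref": "T1w",
            "tp_date": surgery,
            "tp_ring": _num(rng, 50, 90),
            "tp_arc": _num(rng, 0, 40),
            "tp_frame": "Leksell G",
            "tp_entry_x": _num(rng, -40, 40, comma=True),
            "tp_entry_y": _num(rng, 20, 60, comma=True),
            "tp_entry_z": _num(rng, 40, 70, comma=True),
            "tp_length": _num(rng, 60, 90),
        })
    for k, side in enumerate(("left", "right")):
        add("mer_summary", "surgery_arm_1", k + 1, {
            "mer_date": surgery,
            "mer_side": side,
            "mer_system": "LeadPoint",
            "mer_ntracks": "3",
            "mer_track": rng.choice(["central", "anterior", "lateral"]),
            "mer_offset": _num(rng, -2, 2, comma=True),
            "mer_ndepths": "10",
            "mer_depth": _num(rng, -10, 0, comma=True),
            "mer_rate": _num(rng, 5, 80),
            "mer_rms": _num(rng, 5, 40),
            "mer_class": rng.choice(["STN", "SNr", "thalamus", "zona incerta"]),
        })
    for k in range(3):
        add("stimulation_test", "surgery_arm_1", k + 1, {
            "st_date": surgery,
            "st_setting": "intra-operative",
            "st_side": rng.choice(["left", "right"]),
            "st_rater": rng.choice(["rater A", "rater B"]),
            "st_contact": f"C{k}",
            "st_type": "monopolar",
            "st_amp": _num(rng, 0.5, 4.5, comma=True),
            "st_pw": "60",
            "st_freq": "130",
            "st_dur": _num(rng, 10, 60),
            "st_symptom": "tremor" if disease_code == "1" else "rigidity",
            "st_baseline": _num(rng, 2, 4),
            "st_score": _num(rng, 0, 2),
            "st_improv": _num(rng, 20, 95),
            "st_se_desc": rng.choice(["none", "paresthesia", "dysarthria"]),
            "st_se_sev": rng.choice(["none", "mild", "moderate"]),
            "st_se_thresh": _num(rng, 3, 6, comma=True),
        })
    for k, side in enumerate(("left", "right")):
        add("implanted_position", "surgery_arm_1", k + 1, {
            "ip_model": "3389",
            "ip_side": side,
            "ip_x": _num(rng, -15, 15, comma=True),
            "ip_y": _num(rng, -10, 5, comma=True),
            "ip_z": _num(rng, -12, 0, comma=True),
            "ip_dev": _num(rng, 0, 2, comma=True),
            "ip_date": surgery,
            "ip_contact": "C1",
            "ip_cx": _num(rng, -15, 15, comma=True),
            "ip_cy": _num(rng, -10, 5, comma=True),
            "ip_cz": _num(rng, -12, 0, comma=True),
        })
    for k in range(2):
        add("postop_screening", "postop_arm_1", k + 1, {
            "ps_date": "01.09.2022",
            "ps_months": str(3 * (k + 1)),
            "ps_status": rng.choice(["improved", "stable"]),
            "ps_adverse": rng.choice(["none", "transient dizziness"]),
            "ps_battery": "ok",
            "ps_medchange": rng.choice(["none", "reduced"]),
            "cs_date": "01.09.2022",
            "cs_mode": "monopolar",
            "cs_amp": _num(rng, 1, 4, comma=True),
            "cs_pw": "60",
            "cs_freq": "130",
            "cs_batt": _num(rng, 60, 100),
            "cs_contact": "C1",
            "cs_polarity": "cathode",
            "cs_fraction": "100",
        })
    return rows


# Column order of the export CSV is fixed for byte-level determinism.
def _export_columns(rows: list[dict]) -> list[str]:
    cols = ["record_id", "redcap_event_name", "redcap_repeat_instrument", "redcap_repeat_instance"]
    seen = set(cols)
    for row in rows:
        for c in row:
            if c not in seen:
                cols.append(c)
                seen.add(c)
    return cols


def _mapping_doc() -> dict:
    num = {"type": "number"}
    coord = {"type": "number", "min": -100, "max": 100}
    dec = {"kind": "decimal-normalize"}
    date = {"kind": "date-normalize"}

    def e(instrument, fieldname, table, column, clean=None, validate=None, required=False):
        entry = {"instrument": instrument, "field": fieldname, "table": table, "column": column}
        if clean:
            entry["clean"] = clean
        if validate:
            entry["validate"] = validate
        if required:
            entry["required"] = True
        return entry

    entries = [
        e("patient_information", "pi_center", "Patients", "center",
          {"kind": "code-to-label", "codes": {"1": "Basel", "2": "ClermontFerrand"}}, required=True),
        e("patient_information", "pi_disease", "Patients", "disease",
          {"kind": "code-to-label", "codes": {"1": "ET", "2": "PD"}},
          {"choices": ["ET", "PD", "other"]}, required=True),
        e("patient_information", "pi_sex", "Patients", "sex",
          {"kind": "code-to-label", "codes": {"0": "F", "1": "M"}}),
        e("patient_information", "pi_age", "Patients", "age_at_surgery", dec,
          {"type": "number", "min": 18, "max": 100}),
        e("patient_information", "pi_surgery_date", "Patients", "date_of_surgery", date,
          {"type": "date"}),
        e("patient_information", "pi_handedness", "Patients", "handedness"),
        e("patient_information", "pi_diag_year", "Patients", "diagnosis_year",
          validate={"type": "integer", "min": 1950, "max": 2030}),
        e("patient_information", "pi_history", "Patients", "medical_history"),
        e("preop_evaluation", "pre_eval_date", "ClinicalEvalTremor", "eval_date", date),
        e("preop_evaluation", "pre_scale", "ClinicalEvalTremor", "scale_name"),
        e("preop_evaluation", "pre_tremor", "ClinicalEvalTremor", "tremor_score", dec, num),
        e("preop_evaluation", "pre_handwriting", "ClinicalEvalTremor", "handwriting_score", dec, num),
        e("preop_evaluation", "pre_spiral", "ClinicalEvalTremor", "spiral_score", dec, num),
        e("preop_evaluation", "pre_updrs_total", "ClinicalEvalUpdrs", "part_iii_total", dec, num),
        e("preop_evaluation", "pre_rigidity", "ClinicalEvalUpdrs", "rigidity_score", dec, num),
        e("preop_evaluation", "pre_brady", "ClinicalEvalUpdrs", "bradykinesia_score", dec, num),
        e("preop_evaluation", "pre_axial", "ClinicalEvalUpdrs", "axial_score", dec, num),
        e("preop_evaluation", "pre_med_state", "ClinicalEvalUpdrs", "med_state"),
        e("postop_evaluation", "post_eval_date", "ClinicalEvalTremor", "eval_date", date),
        e("postop_evaluation", "post_scale", "ClinicalEvalTremor", "scale_name"),
        e("postop_evaluation", "post_tremor", "ClinicalEvalTremor", "tremor_score", dec, num),
        e("postop_evaluation", "post_handwriting", "ClinicalEvalTremor", "handwriting_score", dec, num),
        e("postop_evaluation", "post_spiral", "ClinicalEvalTremor", "spiral_score", dec, num),
        e("postop_evaluation", "post_updrs_total", "ClinicalEvalUpdrs", "part_iii_total", dec, num),
        e("postop_evaluation", "post_rigidity", "ClinicalEvalUpdrs", "rigidity_score", dec, num),
        e("postop_evaluation", "post_brady", "ClinicalEvalUpdrs", "bradykinesia_score", dec, num),
        e("postop_evaluation", "post_axial", "ClinicalEvalUpdrs", "axial_score", dec, num),
        e("postop_evaluation", "post_med_state", "ClinicalEvalUpdrs", "med_state"),
        e("postop_evaluation", "post_qol_instrument", "ClinicalEvalQol", "instrument_name"),
        e("postop_evaluation", "post_qol_total", "ClinicalEvalQol", "total_score", dec, num),
        e("postop_evaluation", "post_qol_mobility", "ClinicalEvalQol", "mobility_score", dec, num),
        e("postop_evaluation", "post_qol_adl", "ClinicalEvalQol", "adl_score", dec, num),
        e("medications", "med_visit_date", "ClinicalDataGeneral", "visit_date", date),
        e("medications", "med_visit_type", "ClinicalDataGeneral", "visit_type"),
        e("medications", "med_name", "Medications", "drug_name", required=True),
        e("medications", "med_dose", "Medications", "dose_mg", dec, {"type": "number", "min": 0}),
        e("medications", "med_freq", "Medications", "frequency_per_day", dec, num),
        e("medications", "med_route", "Medications", "route"),
        e("medications", "med_start", "Medications", "start_date", date),
        e("medications", "med_ongoing", "Medications", "ongoing", validate={"type": "integer"}),
        e("imaging_metadata", "im_modality", "ImagingAcquisitions", "modality",
          validate={"choices": ["MRI", "CT"]}, required=True),
        e("imaging_metadata", "im_session", "ImagingAcquisitions", "session_label"),
        e("imaging_metadata", "im_date", "ImagingAcquisitions", "acquisition_date", date),
        e("imaging_metadata", "im_scanner", "ImagingAcquisitions", "scanner_model"),
        e("imaging_metadata", "im_field", "ImagingAcquisitions", "field_strength_t", dec, num),
        e("imaging_metadata", "im_slices", "ImagingAcquisitions", "n_slices",
          validate={"type": "integer", "min": 1}),
        e("imaging_metadata", "im_available", "ImagingAcquisitions", "available",
          validate={"type": "integer"}),
        e("targeting_plan", "tp_structure", "TargetingPlans", "target_structure", required=True),
        e("targeting_plan", "tp_side", "TargetingPlans", "hemisphere"),
        e("targeting_plan", "tp_x", "TargetingPlans", "x_mm", dec, coord, required=True),
        e("targeting_plan", "tp_y", "TargetingPlans", "y_mm", dec, coord, required=True),
        e("targeting_plan", "tp_z", "TargetingPlans", "z_mm", dec, coord, required=True),
        e("targeting_plan", "tp_acpc", "TargetingPlans", "ac_pc_based", validate={"type": "integer"}),
        e("targeting_plan", "tp_imaging_ref", "TargetingPlans", "imaging_ref"),
        e("targeting_plan", "tp_date", "TargetingPlans", "plan_date", date),
        e("targeting_plan", "tp_ring", "ArcSettings", "ring_angle_deg", dec, num),
        e("targeting_plan", "tp_arc", "ArcSettings", "arc_angle_deg", dec, num),
        e("targeting_plan", "tp_frame", "ArcSettings", "frame_type"),
        e("targeting_plan", "tp_entry_x", "PlannedTrajectories", "entry_x_mm", dec, coord),
        e("targeting_plan", "tp_entry_y", "PlannedTrajectories", "entry_y_mm", dec, coord),
        e("targeting_plan", "tp_entry_z", "PlannedTrajectories", "entry_z_mm", dec, coord),
        e("targeting_plan", "tp_length", "PlannedTrajectories", "length_mm", dec, num),
        e("mer_summary", "mer_date", "MerSessions", "session_date", date),
        e("mer_summary", "mer_side", "MerSessions", "hemisphere"),
        e("mer_summary", "mer_system", "MerSessions", "recording_system"),
        e("mer_summary", "mer_ntracks", "MerSessions", "n_tracks", validate={"type": "integer"}),
        e("mer_summary", "mer_track", "MerTracks", "track_label", required=True),
        e("mer_summary", "mer_offset", "MerTracks", "entry_offset_mm", dec, num),
        e("mer_summary", "mer_ndepths", "MerTracks", "n_depths", validate={"type": "integer"}),
        e("mer_summary", "mer_depth", "MerDepths", "depth_mm", dec, num),
        e("mer_summary", "mer_rate", "MerDepths", "firing_rate_hz", dec, {"type": "number", "min": 0}),
        e("mer_summary", "mer_rms", "MerDepths", "rms_amplitude_uv", dec, {"type": "number", "min": 0}),
        e("mer_summary", "mer_class", "MerDepths", "classification"),
        e("stimulation_test", "st_date", "StimulationSessions", "session_date", date),
        e("stimulation_test", "st_setting", "StimulationSessions", "setting",
          validate={"choices": ["intra-operative", "post-operative"]}),
        e("stimulation_test", "st_side", "StimulationSessions", "hemisphere"),
        e("stimulation_test", "st_rater", "StimulationSessions", "rater"),
        e("stimulation_test", "st_contact", "Stimulations", "contact_label", required=True),
        e("stimulation_test", "st_type", "Stimulations", "stim_type"),
        e("stimulation_test", "st_amp", "Stimulations", "amplitude_ma", dec,
          {"type": "number", "min": 0, "max": 25.5}),
        e("stimulation_test", "st_pw", "Stimulations", "pulse_width_us", dec,
          {"type": "number", "min": 10, "max": 450}),
        e("stimulation_test", "st_freq", "Stimulations", "frequency_hz", dec,
          {"type": "number", "min": 2, "max": 250}),
        e("stimulation_test", "st_dur", "Stimulations", "duration_s", dec, num),
        e("stimulation_test", "st_symptom", "StimulationEffects", "symptom", required=True),
        e("stimulation_test", "st_baseline", "StimulationEffects", "baseline_score", dec, num),
        e("stimulation_test", "st_score", "StimulationEffects", "score", dec, num),
        e("stimulation_test", "st_improv", "StimulationEffects", "improvement_pct", dec,
          {"type": "number", "min": -100, "max": 100}),
        e("stimulation_test", "st_se_desc", "StimulationSideEffects", "description", required=True),
        e("stimulation_test", "st_se_sev", "StimulationSideEffects", "severity"),
        e("stimulation_test", "st_se_thresh", "StimulationSideEffects", "threshold_ma", dec, num),
        e("implanted_position", "ip_model", "ImplantedPositions", "electrode_model", required=True),
        e("implanted_position", "ip_side", "ImplantedPositions", "hemisphere"),
        e("implanted_position", "ip_x", "ImplantedPositions", "x_mm", dec, coord, required=True),
        e("implanted_position", "ip_y", "ImplantedPositions", "y_mm", dec, coord, required=True),
        e("implanted_position", "ip_z", "ImplantedPositions", "z_mm", dec, coord, required=True),
        e("implanted_position", "ip_dev", "ImplantedPositions", "deviation_mm", dec, num),
        e("implanted_position", "ip_date", "ImplantedPositions", "implant_date", date),
        e("implanted_position", "ip_contact", "ImplantedContacts", "contact_label", required=True),
        e("implanted_position", "ip_cx", "ImplantedContacts", "x_mm", dec, coord),
        e("implanted_position", "ip_cy", "ImplantedContacts", "y_mm", dec, coord),
        e("implanted_position", "ip_cz", "ImplantedContacts", "z_mm", dec, coord),
        e("postop_screening", "ps_date", "PostopScreenings", "screening_date", date),
        e("postop_screening", "ps_months", "PostopScreenings", "months_post_op", dec, num),
        e("postop_screening", "ps_status", "PostopScreenings", "symptom_status"),
        e("postop_screening", "ps_adverse", "PostopScreenings", "adverse_events"),
        e("postop_screening", "ps_battery", "PostopScreenings", "battery_status"),
        e("postop_screening", "ps_medchange", "PostopScreenings", "medication_change"),
        e("postop_screening", "cs_date", "ChronicSettings", "setting_date", date),
        e("postop_screening", "cs_mode", "ChronicSettings", "stimulation_mode"),
        e("postop_screening", "cs_amp", "ChronicSettings", "amplitude_ma", dec,
          {"type": "number", "min": 0, "max": 25.5}),
        e("postop_screening", "cs_pw", "ChronicSettings", "pulse_width_us", dec, num),
        e("postop_screening", "cs_freq", "ChronicSettings", "frequency_hz", dec, num),
        e("postop_screening", "cs_batt", "ChronicSettings", "battery_level_pct", dec,
          {"type": "number", "min": 0, "max": 100}),
        e("postop_screening", "cs_contact", "ChronicContacts", "contact_label"),
        e("postop_screening", "cs_polarity", "ChronicContacts", "polarity"),
        e("postop_screening", "cs_fraction", "ChronicContacts", "fraction_pct", dec,
          {"type": "number", "min": 0, "max": 100}),
    ]
    return {"version": 1, "instruments": list(INSTRUMENTS), "entries": entries}


def _write_nifti(path: Path, seed_bytes: int) -> None:
    """Minimal valid uncompressed volume; content varies with seed_bytes."""
    data = (np.arange(64, dtype=np.uint8).reshape(4, 4, 4) + seed_bytes % 191)
    img = nib.Nifti1Image(data.astype(np.uint8), affine=np.eye(4))
    img.to_filename(str(path))


def _image_plan(config: CohortConfig, codes: list[str]) -> list[dict]:
    plan: list[dict] = []
    for i, code in enumerate(codes):
        for session in config.sessions:
            for suffix, modality in (("T1w", "MRI"), ("CT", "CT")):
                acq = "ppp" if (session, suffix) == ("pre", "T1w") else ""
                plan.append(dict(
                    source_path=f"images/{code}_{session}_{suffix}.nii".lower(),
                    subject=code, subject_type="Patient", session=session,
                    acquisition=acq, suffix=suffix, extension=".nii",
                    category="anat-raw", structure_label="", modality=modality,
                ))
        plan.append(dict(
            source_path=f"images/{code}_stn.nii".lower(),
            subject=code, subject_type="Patient", session="pre", acquisition="",
            suffix="dseg", extension=".nii", category="Segmentations",
            structure_label="STN", modality="MRI",
        ))
        plan.append(dict(
            source_path=f"images/{code}_warp.txt".lower(),
            subject=code, subject_type="Patient", session="pre", acquisition="",
            suffix="xfm", extension=".txt", category="Transforms",
            structure_label="", modality="",
        ))
    if codes:
        plan.append(dict(
            source_path="images/atlas_v1_stn.nii",
            subject=_bids.ATLAS_SUBJECT, subject_type="Atlas", session="v1",
            acquisition="", suffix="dseg", extension=".nii",
            category="Segmentations", structure_label="STN", modality="MRI",
        ))
        plan.append(dict(
            source_path="images/electrode_3389.txt",
            subject=f"{_bids.ELECTRODE_PREFIX}3389", subject_type="Electrode",
            session="", acquisition="", suffix="model", extension=".txt",
            category="ElectrodeModel", structure_label="", modality="",
        ))
    return plan


_MANIFEST_COLUMNS = (
    "source_path", "subject", "subject_type", "session", "acquisition",
    "suffix", "extension", "category", "structure_label", "modality",
)


def generate_cohort(config: CohortConfig, out: str | Path) -> dict:
    """Write export.csv, mapping.yaml, manifest.csv and the images/ tree.

    Returns a dict of the produced paths. Identical (config, seed) runs
    produce byte-identical files.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(config.seed)
    codes = [_patient_code(config, i) for i in range(config.n_patients)]

    diseases = list(config.disease_weights)
    weights = [config.disease_weights[d] for d in diseases]
    rows: list[dict] = []
    for i, code in enumerate(codes):
        disease = rng.choices(diseases, weights=weights)[0]
        rows.extend(_rows_for_patient(rng, code, i % len(config.centers), disease))

    export_csv = out / "export.csv"
    template = _rows_for_patient(random.Random(0), "X", 0)  # column universe
    columns = _export_columns(template)
    with export_csv.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, lineterminator="\n")
        writer.writeheader()
        for row in rows:
            writer.writerow({c: row.get(c, "") for c in columns})

    mapping_path = out / "mapping.yaml"
    mapping_path.write_text(yaml.safe_dump(_mapping_doc(), sort_keys=False))

    plan = _image_plan(config, codes)
    images_dir = out / "images"
    images_dir.mkdir(exist_ok=True)
    for k, entry in enumerate(plan):
        src = out / entry["source_path"]
        if entry["extension"] == ".nii":
            _write_nifti(src, seed_bytes=config.seed * 131 + k)
        else:
            src.write_text("1 0 0 0\n0 1 0 0\n0 0 1 0\n0 0 0 1\n")
        sidecar = {"Modality": entry["modality"]} if entry["modality"] else {}
        if entry["subject_type"] == "Electrode":
            sidecar = {
                "Manufacturer": "Medtronic", "NContacts": 4, "ContactLengthMm": 1.5,
                "SpacingMm": 0.5, "LeadDiameterMm": 1.27, "SpanMm": 7.5,
                "Material": "Pt-Ir",
            }
        if entry["suffix"] == "T1w":
            sidecar.update({"EchoTime": 3.2, "RepetitionTime": 2300.0,
                            "AcquisitionTime": "08:30:00"})
        if sidecar:
            (out / entry["source_path"]).with_suffix(".json").write_text(
                json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
            )

    manifest_path = out / "manifest.csv"
    with manifest_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(_MANIFEST_COLUMNS), lineterminator="\n")
        writer.writeheader()
        for entry in plan:
            writer.writerow({c: entry.get(c, "") for c in _MANIFEST_COLUMNS})

    return {
        "export_csv": export_csv,
        "mapping": mapping_path,
        "manifest": manifest_path,
        "images_dir": images_dir,
        "patient_codes": codes,
    }


def corrupt(artifact: str | Path, mode: str, out: str | Path | None = None) -> Path:
    """Copy a generated artifact with exactly one deterministic defect.

    CSV modes operate on an export CSV; ``bad-filename`` operates on a BIDS
    root directory (the first image file, in sorted order, is renamed to
    ``scan1`` + its extension). The original is never touched.
    """
    artifact = Path(artifact)
    if mode not in CORRUPT_MODES:
        raise DbsCohortError(f"unknown corrupt mode {mode!r}")

    if mode == "bad-filename":
        dest = Path(out) if out else artifact.parent / (artifact.name + "-corrupt")
        if dest.exists():
            shutil.rmtree(dest)
        shutil.copytree(artifact, dest)
        images = sorted(p for p in dest.rglob("*") if p.is_file() and p.suffix != ".json"
                        and p.name != "dataset_description.json")
        if not images:
            raise DbsCohortError(f"no image files under {artifact}")
        victim = images[0]
        _, ext = _bids.split_extension(victim.name)
        victim.rename(victim.parent / f"scan1{ext}")
        return dest

    dest = Path(out) if out else artifact.with_name(artifact.stem + "-corrupt.csv")
    with artifact.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        table = list(reader)
    header, body = table[0], table[1:]
    if mode == "bad-coordinate":
        col = header.index("tp_x")
        for row in body:
            if row[col].strip():
                row[col] = "abc"
                break
        else:
            raise DbsCohortError("no targeting X value to corrupt")
    elif mode == "missing-column":
        col = header.index("record_id")
        header = header[:col] + header[col + 1:]
        body = [row[:col] + row[col + 1:] for row in body]
    elif mode == "duplicate-key":
        if not body:
            raise DbsCohortError("no data row to duplicate")
        body = [body[0]] + body
    with dest.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(body)
    return dest


def run_pipeline(cohort: dict, db_path: str | Path, root: str | Path) -> dict:
    """End-to-end: init-db → ingest-redcap → ingest-images → derive.

    After the two ingests, each patient's raw pre-operative T1w is linked
    through their warp file to the v1 atlas space, so a cohort with at least
    one patient populates every table group including Transformations.
    Returns the reports and the violation list.
    """
    db = _schema.init_db(db_path)
    records = _redcap.parse_redcap_export(cohort["export_csv"])
    mapping = _redcap.load_mapping(cohort["mapping"], db)
    redcap_report = _redcap.ingest(records, mapping, db)
    image_report = _bids.ingest_images(cohort["manifest"], db, root)

    root = Path(root)
    atlas = db.execute(
        "SELECT f.file_id FROM Files f JOIN Bids b ON b.file_id = f.file_id"
        " WHERE b.subject_label = ? AND b.session_label = 'v1' AND b.suffix = 'dseg'",
        (_bids.ATLAS_SUBJECT,),
    ).fetchone()
    derived_ids = []
    if atlas:
        for code in cohort["patient_codes"]:
            pair = db.execute(
                "SELECT f.file_id, f.file_type, f.path FROM Files f"
                " JOIN Bids b ON b.file_id = f.file_id"
                " JOIN Patients p ON p.patient_id = f.patient_id"
                " WHERE p.patient_code = ? AND b.suffix IN ('xfm', 'T1w')"
                " AND b.session_label = 'pre' AND b.space_label IS NULL"
                " ORDER BY b.suffix", (code,),
            ).fetchall()
            by_suffix = {("warp" if r["file_type"] == "warp" else "T1w"): r for r in pair}
            if "warp" not in by_suffix or "T1w" not in by_suffix:
                continue
            tid = _prov.register_transformation(
                db, by_suffix["warp"]["file_id"], atlas["file_id"]
            )
            derived_ids.append(
                _prov.register_derived_image(
                    db, root, by_suffix["T1w"]["file_id"], tid,
                    _bids.PATIENT_TO_ATLAS,
                    payload=root / by_suffix["T1w"]["path"],
                )
            )
    violations = _bids.validate_tree(root, db)
    return {
        "db": db,
        "redcap_report": redcap_report,
        "image_report": image_report,
        "derived_file_ids": derived_ids,
        "violations": violations,
    }
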