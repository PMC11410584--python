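# dbscohort

Integrated research data management for deep brain stimulation (DBS)
cohorts. DBS studies accumulate heterogeneous data per patient — clinical
evaluations and stimulation-test scores captured in an electronic data
capture (EDC) system such as REDCap, pre/post-operative CT and MRI volumes,
targeting coordinates, microelectrode-recording summaries, and the
derivatives that group analysis produces (segmentations, warps, volumes of
tissue activated, atlas-space projections). `dbscohort` keeps all of it in
one place for the researchers who run those analyses:

- a **patient-centric relational schema** in a single SQLite file: 28 tables
  with 230 columns and 33 foreign-key relationships, organised into content
  groups (clinical data, imaging data, stimulation-configuration
  evaluations, microelectrode recordings, targeting, chronic stimulation
  configuration, implanted position, electrodes) around a central
  `Patients` table;
- a **BIDS raw + derivatives image layout** where derivative folders name
  content (`Segmentations`, `PatientInAtlas`, `AtlasInPatient`,
  `Transforms`, …) and cross-space provenance is encoded in the filename:
  transforming `sub-<id>_ses-<ses>_acq-<a>_T1w.nii.gz` into the space of
  atlas version *v* yields `sub-<id>_space-<v>_ses-<ses>_acq-<a>_T1w.nii.gz`
  under `derivatives/sub-<id>/PatientInAtlas`;
- **ingestion pipelines**: `ingest-redcap` routes a longitudinal REDCap CSV
  export into the schema through declarative mapping files with regex
  cleaning and field validation; `ingest-images` copies imaging files into
  the BIDS tree and registers paths, BIDS entities and anatomical labels in
  the database;
- a **provenance and query layer**: every file row can point to the file it
  was derived from (`source_id`) and the spatial transformation that
  produced it (`transformation_id` → warp file + target-space image), so
  the full lineage of any derivative is one query away, and
  `select_files` answers group-analysis selections ("all files of ET
  patients in atlas space v1") in a single call;
- a **seeded synthetic cohort generator** so everything is testable
  end-to-end without clinical data.

## Worked example

```
$ dbscohort fixture --out cohort --n 2 --seed 5 > /dev/null
$ dbscohort init-db --db study.db
$ dbscohort stats --db study.db
tables             28
fields            230
relationships      33
$ dbscohort ingest-redcap --db study.db --csv cohort/export.csv --mapping cohort/mapping.yaml
{
  "inserted": 94,
  "updated": 0,
  "rejected": 0,
  "rejections": []
}
$ dbscohort ingest-images --db study.db --root bids --manifest cohort/manifest.csv
{
  "inserted": 14,
  "updated": 0,
  "rejected": 0,
  "rejections": []
}
$ dbscohort validate --db study.db --root bids
INFO tree is valid
```

The two patients' 19 export rows each (10 instruments, several repeating)
became 94 relational rows; the 14 manifest items (4 raw scans, one STN
label and one warp per patient, a shared atlas-space segmentation and an
electrode model file) were renamed into the BIDS tree and registered.
Re-running either ingest reports `inserted: 0` — both pipelines upsert on
the source key. A query then selects files by joint clinical/imaging
predicates:

```
$ dbscohort query --db study.db --disease ET --file-type label --json
```

returns the STN label files of the ET patients only, each row joined with
patient code, center, disease and the parsed BIDS entities.

From Python the same surface is `dbscohort.init_db`, `ingest`,
`ingest_images`, `select_files`, `lineage`, `patient_bundle`,
`register_transformation`, `register_derived_image`.

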