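# Methods

## The data model

The database is a single SQLite file. SQLite was chosen for the same
reasons it suits desk-scale clinical research: zero server administration,
one portable file per study, and full SQL. Two consequences shape the
implementation: SQLite leaves foreign-key enforcement off by default, so
every connection the package opens switches it on (`PRAGMA foreign_keys`),
and files created by the package are stamped with an `application_id`
pragma so `init_db`/`connect` can refuse foreign files instead of silently
writing into them.

The schema is shipped as one canonical DDL script (`src/dbscohort/
schema.sql`) and is the single source of truth: 28 tables, 230 columns, 33
foreign-key relationships. `schema_stats` always reports these numbers by
catalog introspection (`sqlite_master`, `PRAGMA table_info`,
`PRAGMA foreign_key_list`), never from constants, which turns the
structural claim into a checkable property of the artifact. Design choices
within the schema:

- Surrogate integer primary keys everywhere; the study code
  (`Patients.patient_code`) is a separate unique column, so joins are
  independent of site identifier conventions.
- Enumerations (disease ∈ {ET, PD, other}, sex, session labels,
  stimulation setting) are constrained text columns (`CHECK ... IN`), not
  lookup tables — the database file stays self-describing and portable.
- Column totals count every column of every user table, primary and
  foreign keys included; each relationship is one foreign-key column, so
  the per-column and per-link readings of the relationship count coincide.
- Every table group except `Electrodes` contains at least one table with a
  direct foreign key to `Patients`; the electrode catalog instead links to
  `Files` (electrode model files used by field simulations).
- Imaging is exactly four tables. `Files` holds path (relative to the BIDS
  root, so database files move between machines), patient/electrode link,
  general file type, and the two lineage pointers. `Bids` and `Labels` use
  the `Files` id as their own primary key (1:1 extension tables). X/Y/Z
  coordinate columns carry a ±100 mm sanity `CHECK`, mirroring the entry
  validation on the clinical forms.

## REDCap ingestion

The supported export dialect is the raw longitudinal CSV (`record_id`,
`redcap_event_name`, `redcap_repeat_instrument`, `redcap_repeat_instance`
plus instrument fields); missing repeat columns degrade gracefully to the
classic export. A pull via the REDCap API is deliberately out of scope:
the CSV file is the contract, and anything that writes that dialect can
feed the pipeline.

Mapping files are YAML: an instrument registry plus entries
`(instrument, field) → (table, column)` with an optional cleaning rule —
`identity`, `regex-substitute`, `decimal-normalize` (comma decimal → dot),
`date-normalize` (to ISO), `code-to-label` (injective code table) — a
validation rule (type, range, vocabulary, length) and a required flag.
The whole mapping is validated against the live schema before any write;
a structural error aborts with the database untouched.

Ingestion walks target tables in foreign-key dependency order. One export
row may fan out into several tables (a stimulation-test row produces a
session row, a stimulation row, an effect row and a side-effect row, wired
together as they are created); rejection granularity is the whole target
row — a row with one invalid cell writes nothing to that table, and child
rows whose parent was rejected are rejected too rather than orphaned.
Rejections are data (key, field, reason) in the report, never exceptions.
Every written row stores its source key
(`record|event|instrument|instance|table`), which makes re-ingestion an
upsert: unchanged input inserts and updates nothing; edited input updates
in place. Rows are processed in sorted key order so surrogate-key
allocation is deterministic.

## Image layout and naming

Filename grammar: underscore-separated `key-label` entities followed by a
suffix, with labels restricted to `[A-Za-z0-9]+` and extensions drawn from
{`.nii.gz`, `.nii`, `.json`, `.h5`, `.txt`}. Emission order is fixed as
`sub, space, ses, acq` — note `space` before `ses`, the order this layout
documents for its transformed files, which differs from canonical BIDS
entity ordering; the parser accepts entities in any order, so canonical
files parse too. Round-tripping (`format∘parse` and `parse∘format`) is
property-tested.

Derivatives are grouped as `derivatives/sub-<id>/<Category>/`, with no
subject-type directory level; subject type is carried by the database and
by reserved id conventions (`ATLAS` for the common space, `ELEC*` for
electrode models). Atlas versioning uses `ses-<version>` on atlas-subject
files and `space-<version>` on files transformed into that atlas. The two
cross-space categories are filed under the *patient* subject in both
directions (`PatientInAtlas`, `AtlasInPatient`), so per-patient folders
list everything concerning that patient. Category names beyond the core
three (`Segmentations`, `PatientInAtlas`, `AtlasInPatient`) —
`Trajectories`, `VTA`, `Conductivity`, `Transforms`, `ElectrodeModel` —
are package-defined to cover the analysis data types of a DBS pipeline.

Images are opaque payloads: ingestion copies (never moves or links) files
and reads only sidecar JSON for metadata; voxel data, orientation and
indexing conventions are never interpreted. Idempotence is content-based:
an identical file at its resolved path is skipped, a different file at the
same path is a hard conflict. `validate_tree` re-derives every file's
expected location from its parsed name and folder context and
cross-checks the filesystem against the `Files` table in both directions.

## Provenance

`Files.source_id` forms a forest (checked acyclic at write time by ancestor
walk, and bounded at read time), and `transformation_id` attaches the warp
+ target-space image pair that produced a derivative. `register_derived_image`
is the one-call path: given a source image, a transformation and a
direction it derives the output name and category, resolves the path,
optionally installs the produced image, and registers Files + Bids rows
with full lineage. Deleting a file with registered descendants requires an
explicit cascade. `select_files` is a single SQL join with conjunctive
predicates; its contract is equality with a brute-force filter over the
materialised join, enforced by tests across seeds and by the acceptance
script.

## Synthetic cohorts

`generate_cohort` emulates a two-center ET/PD cohort: per patient, 19
export rows covering exactly ten instruments (patient information, pre-
and post-operative clinical evaluations, medications, imaging metadata,
targeting plan, MER summaries, stimulation tests ×3, implanted position
×2, post-operative screening ×2 — the screening form also records the
chronic stimulation configuration in use), plus pre/post CT and MRI
volumes, one STN label, one warp per patient, a shared atlas-space
segmentation and an electrode model file. Default sizes (n = 5 for
end-to-end checks, 2 centers, sessions pre/post) keep the whole pipeline
in the low seconds while touching every table.

Values are drawn uniformly within clinically plausible ranges (ages 45–80,
amplitudes 0.5–4.5 mA, pulse width 60 µs, frequency 130 Hz, coordinates
within ±40 mm); numbers are written with comma decimals and dates in
`dd.mm.yyyy` specifically to exercise the cleaning rules. NIfTI payloads
are minimal 4×4×4 volumes written uncompressed (`.nii`) so identical
(config, seed) runs are byte-identical — gzip streams would embed
timestamps. Record ids embed the seed, so different seeds cannot collide.

What the fixtures do **not** emulate: epidemiologically realistic value
distributions or correlations, realistic anatomy or image content, MER
waveforms, label-export dialects, free-text messiness beyond the injected
corruption modes, or multi-event longitudinal depth beyond
baseline/pre/surgery/post. Green end-to-end tests therefore demonstrate
the plumbing — routing, cleaning, naming, provenance, querying — not
robustness to every real-world REDCap project layout.

## Numerical and procedural choices

- Cleaning is deterministic and total: empty cells are "missing" (distinct
  from rejected); missing required fields reject the row.
- Date parsing accepts ISO, `dd.mm.yyyy` and `dd/mm/yyyy` unless the
  mapping pins a format.
- Query results are ordered by (subject id, path); serialization column
  order is fixed and documented in `provenance.QUERY_COLUMNS`.
- Corruption modes pick their victim deterministically (first eligible
  cell/row/file in sorted order) so negative-path tests are stable.
- CLI exit codes: 0 success, 1 data/validation error, 2 usage error; data
  on stdout, messages on stderr.

## Known limitations

- No schema migration between versions; `init_db` is idempotent on its own
  schema and refuses anything else.
- Cross-center record-id collisions are not merged; the fixture id scheme
  makes them impossible, and real deployments should prefix center codes.
- MER storage is per-depth summary rows with an optional file reference;
  raw waveforms are managed as files only.
- `register_derived_image` registers bookkeeping even when the produced
  image has not been written yet; until then `validate_tree` reports the
  dangling reference — by design, as the validator is the tool that finds
  such gaps.
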