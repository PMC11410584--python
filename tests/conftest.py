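import pytest

from dbscohort.fixtures import CohortConfig, generate_cohort, run_pipeline


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """A small synthetic cohort (n=3, seed=7): export CSV, mapping, images."""
    out = tmp_path_factory.mktemp("cohort")
    return generate_cohort(CohortConfig(n_patients=3, seed=7), out)


@pytest.fixture(scope="session")
def pipeline(cohort, tmp_path_factory):
    """The cohort run end-to-end: populated db + BIDS tree + reports."""
    base = tmp_path_factory.mktemp("pipeline")
    result = run_pipeline(cohort, base / "study.db", base / "bids")
    result["root"] = base / "bids"
    result["db_path"] = base / "study.db"
    yield result
    result["db"].close()
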