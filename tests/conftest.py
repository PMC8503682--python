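"""Shared fixtures: a generated default study, its ETL'd database."""


import pytest
from hypothesis import settings

from genovault import datastore, etl
from genovault.synthetic import StudyConfig, write_study

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study(tmp_path_factory) -> dict:
    """Default synthetic study (seed 42): file tree, truth, and database."""
    root = tmp_path_factory.mktemp("study42")
    config = StudyConfig(seed=42)
    manifest, truth = write_study(config, root / "files")
    db = etl.etl_study(root / "files", root / "study.db")
    yield {
        "config": config,
        "dir": root / "files",
        "manifest": manifest,
        "truth": truth,
        "db": db,
        "db_path": root / "study.db",
    }
    db.close()


@pytest.fixture()
def fresh_db(tmp_path) -> datastore.StudyDatabase:
    db = datastore.create_database(tmp_path / "fresh.db")
    yield db
    db.close()


@pytest.fixture()
def seeded_db(fresh_db) -> datastore.StudyDatabase:
    """Empty database pre-loaded with two samples of metadata."""
    from genovault.records import StudyMetadataRecord

    records = [
        StudyMetadataRecord(
            record_id=f"M{i}", study_id="S", patient_id=f"P{i}",
            sample_id=sid, tissue_type="T1", assay_type=assay,
            replicate=1, pipeline_name="p", pipeline_version="1",
            reference_build="b",
        )
        for i, (sid, assay) in enumerate(
            [("S1", "rna_seq"), ("S1", "dna_panel"),
             ("S2", "rna_seq"), ("S2", "cnv_lowpass")]
        )
    ]
    datastore.bulk_insert(fresh_db, "study_metadata", records)
    return fresh_db
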