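"""Bundle model: serialisation round trips, integrity checks, adapters."""

import json

import pytest

from paleoaudit.archive_model import (
    AnalysisRecord,
    Attribute,
    BundleIntegrityError,
    BundleParseError,
    FileRef,
    PaperReport,
    RunRecord,
    SampleRecord,
    StudyBundle,
    StudyRecord,
    bundle_to_dict,
    from_ena_filereport,
    load_bundle,
    write_bundle,
)


def _bundle():
    return StudyBundle(
        study=StudyRecord("PRJX1", "title", "desc"),
        samples=[
            SampleRecord("SAMX1", alias="IND1", title="an individual",
                         attributes=[Attribute("tissue", "tooth"),
                                     Attribute("date", "4000 BP", "years")]),
            SampleRecord("SAMX2", alias="IND2"),
        ],
        runs=[
            RunRecord("RUNX1", "SAMX1", library_name="L1",
                      library_construction_protocol="double-stranded",
                      instrument_platform="ILLUMINA", submitted_format="FASTQ",
                      files=[FileRef("r1.fastq")]),
        ],
        analyses=[
            AnalysisRecord("ANAX1", "REFERENCE_ALIGNMENT",
                           linked_run_accessions=["RUNX1"],
                           linked_sample_accessions=["SAMX1"],
                           files=[FileRef("a1.bam")]),
        ],
        paper_report=PaperReport(2, 3, used_capture=True,
                                 previously_published_samples=[("IND1", "SAMOLD")],
                                 total_reported_in_paper=True),
    )


def test_write_load_round_trip_is_identity(tmp_path):
    p = tmp_path / "bundle.json"
    original = _bundle()
    write_bundle(original, p)
    reloaded = load_bundle(p)
    assert bundle_to_dict(reloaded) == bundle_to_dict(original)


def test_write_is_byte_deterministic(tmp_path):
    p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
    write_bundle(_bundle(), p1)
    write_bundle(_bundle(), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_minimal_bundle_has_empty_collections(tmp_path):
    p = tmp_path / "b.json"
    write_bundle(StudyBundle(study=StudyRecord("PRJX2")), p)
    b = load_bundle(p)
    assert (b.samples, b.runs, b.analyses, b.paper_report) == ([], [], [], None)


def test_dangling_sample_reference_rejected(tmp_path):
    b = _bundle()
    b.runs[0].sample_accession = "SAM-MISSING"
    with pytest.raises(BundleIntegrityError, match="SAM-MISSING"):
        write_bundle(b, tmp_path / "b.json")
    doc = bundle_to_dict(_bundle())
    doc["runs"][0]["sample_accession"] = "SAM-MISSING"
    p = tmp_path / "broken.json"
    p.write_text(json.dumps(doc))
    with pytest.raises(BundleIntegrityError):
        load_bundle(p)


def test_duplicate_sample_accessions_rejected(tmp_path):
    b = _bundle()
    b.samples.append(SampleRecord("SAMX1", alias="again"))
    with pytest.raises(BundleIntegrityError, match="duplicate"):
        b.validate()


def test_missing_schema_field_names_offender(tmp_path):
    p = tmp_path / "bad.json"
    p.write_text(json.dumps({"study": {"title": "no accession"}}))
    with pytest.raises(BundleParseError, match="accession"):
        load_bundle(p)


def test_paper_report_count_invariants():
    with pytest.raises(BundleParseError):
        PaperReport(n_samples_analysed=5, n_samples_studied_total=3)
    with pytest.raises(BundleParseError):
        PaperReport(n_samples_analysed=-1)


ENA_HEADER = ("study_accession\trun_accession\tsample_accession\tsample_alias\t"
              "library_name\tinstrument_platform\tsubmitted_format\tfastq_ftp\t"
              "submitted_ftp\tcustom_col")


def test_ena_filereport_rows_become_runs(tmp_path):
    report = tmp_path / "filereport.tsv"
    report.write_text(
        ENA_HEADER + "\n"
        "PRJE1\tERR1\tSAME1\tS1\tL1\tILLUMINA\tFASTQ\tx/ERR1.fastq.gz\t\tv1\n"
        "PRJE1\tERR2\tSAME1\tS1\tL2\tILLUMINA\tBAM\t\tx/ERR2.bam\tv2\n"
    )
    b = from_ena_filereport(report)
    assert len(b.runs) == 2 and len(b.samples) == 1
    assert b.study.accession == "PRJE1"
    assert b.runs[1].submitted_format == "BAM"
    assert b.runs[1].files[0].declared_format == "bam"
    assert b.runs[0].files[0].declared_format == "fastq"
    # unknown columns preserved as run attributes
    assert ("custom_col", "v1") in [(a.tag, a.value) for a in b.runs[0].attributes]


def test_ena_filereport_header_only_gives_zero_runs(tmp_path):
    report = tmp_path / "empty.tsv"
    report.write_text(ENA_HEADER + "\n")
    b = from_ena_filereport(report)
    assert b.runs == [] and b.samples == []


def test_ena_filereport_missing_mandatory_column(tmp_path):
    report = tmp_path / "bad.tsv"
    report.write_text("run_accession\tlibrary_name\nERR1\tL1\n")
    with pytest.raises(BundleParseError, match="sample_accession"):
        from_ena_filereport(report)


def test_biosample_attributes_attached(tmp_path):
    report = tmp_path / "filereport.tsv"
    report.write_text(
        ENA_HEADER + "\nPRJE1\tERR1\tSAME1\tS1\tL1\tILLUMINA\tFASTQ\tx.fq.gz\t\t\n"
    )
    attrs = tmp_path / "biosample.tsv"
    attrs.write_text(
        "sample_accession\ttag\tvalue\tunits\n"
        "SAME1\tgeographic location (latitude)\t52.2\tDD\n"
        "SAME1\ttissue\tpetrous bone\t\n"
    )
    b = from_ena_filereport(report, attrs)
    tags = [(a.tag, a.value) for a in b.samples[0].attributes]
    assert ("tissue", "petrous bone") in tags
    assert b.samples[0].attribute("TISSUE").value == "petrous bone"
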