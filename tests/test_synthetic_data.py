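"""Generator mechanics: determinism, bounds, profiles, planting."""

import numpy as np
import pysam
import pytest

from paleoaudit.archive_model import load_bundle
from paleoaudit.cli_report import compute_file_stats
from paleoaudit.config import AuditConfig
from paleoaudit.seqcheck import collect_seq_stats, infer_hard_filters
from paleoaudit.synthetic_data import (
    ENTAILMENTS,
    VIOLATION_CODES,
    CohortSpec,
    ProfileError,
    Violation,
    ViolationProfile,
    generate_cohort,
    generate_study,
    simulate_reads,
)


def test_simulate_reads_empty_and_bounds():
    assert simulate_reads(0, 1) == []
    reads = simulate_reads(500, 1)
    lengths = [len(r) for r in reads]
    assert min(lengths) >= 25 and max(lengths) <= 120
    assert set("".join(reads)) <= set("ACGT")


def test_simulate_reads_seed_determinism():
    assert simulate_reads(200, 9) == simulate_reads(200, 9)
    assert simulate_reads(200, 9) != simulate_reads(200, 10)


def test_violation_parse_spec_round_trip():
    for text in ["no_geo", "mapq_filter(30)", "invalid_bam(V7)", "under_archive(2)"]:
        assert Violation.parse(text).spec() == text
    with pytest.raises(ProfileError):
        Violation.parse("not_a_code")
    with pytest.raises(ProfileError):
        Violation("no_geo", 3)  # parameter on a parameterless code


def test_entailment_table_covers_every_code():
    assert set(ENTAILMENTS) == VIOLATION_CODES


@pytest.mark.parametrize("a,b", [
    ("no_read_groups", "sm_mismatch"),
    ("no_sm", "multi_sm"),
    ("no_geo", "no_coords"),
    ("no_date", "date_no_c14"),
    ("aligned_only_no_raw", "untrimmed_adapters"),
])
def test_contradictory_profiles_rejected(a, b):
    with pytest.raises(ProfileError):
        ViolationProfile.of(a, b).validate()


def test_bam_codes_require_alignment_archiving():
    with pytest.raises(ProfileError):
        ViolationProfile.of("mapq_filter(30)", archive_alignments=False).validate()


def test_generated_fastq_and_bundle_are_byte_identical_across_runs(tmp_path):
    b1 = generate_study(ViolationProfile.of(), 21, tmp_path / "a", n_reads=800)
    b2 = generate_study(ViolationProfile.of(), 21, tmp_path / "b", n_reads=800)
    d1, d2 = tmp_path / "a" / "SYN0001", tmp_path / "b" / "SYN0001"
    for name in sorted(p.name for p in d1.glob("*.fastq")):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
    assert (d1 / "bundle.json").read_bytes() == (d2 / "bundle.json").read_bytes()
    assert b1.study.accession == b2.study.accession


def test_generated_bam_record_streams_identical_across_runs(tmp_path):
    generate_study(ViolationProfile.of(), 21, tmp_path / "a", n_reads=800)
    generate_study(ViolationProfile.of(), 21, tmp_path / "b", n_reads=800)

    def records(path):
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            return [(r.query_name, r.flag, r.reference_id, r.reference_start,
                     r.mapping_quality, r.query_sequence) for r in af]

    for name in ["SYN0001-SAM1.bam", "SYN0001-SAM2.bam", "SYN0001-SAM3.bam"]:
        assert records(tmp_path / "a" / "SYN0001" / name) == records(
            tmp_path / "b" / "SYN0001" / name)


def test_written_bundle_reloads_identically(tmp_path):
    from paleoaudit.archive_model import bundle_to_dict

    bundle = generate_study(ViolationProfile.of("no_geo"), 5, tmp_path, n_reads=800)
    reloaded = load_bundle(tmp_path / "SYN0001" / "bundle.json")
    assert bundle_to_dict(reloaded) == bundle_to_dict(bundle)


@pytest.mark.parametrize("q", [25, 30, 37])
def test_mapq_filter_planting_detected_at_or_below_trigger(tmp_path, q):
    """Planting property: a MAPQ >= q filter is reported whenever the
    inference trigger sits at or below q and enough reads remain."""
    bundle = generate_study(
        ViolationProfile.of(Violation("mapq_filter", q)), 31,
        tmp_path / f"q{q}", n_reads=2000)
    cfg = AuditConfig(min_confident_n=100)
    stats = compute_file_stats(bundle, tmp_path / f"q{q}" / "SYN0001", cfg)
    bam_stats = [s for s in stats.values() if s.declared_format == "bam"]
    assert bam_stats
    for st in bam_stats:
        sig = infer_hard_filters(st, mapq_trigger=25, length_trigger=30,
                                 min_confident_n=100)
        assert sig.mapq_filtered and sig.mapq_floor >= q
        higher = infer_hard_filters(st, mapq_trigger=q + 1, length_trigger=30,
                                    min_confident_n=100)
        assert not higher.mapq_filtered  # trigger above the planted floor


def test_adapter_planting_fraction_exceeds_threshold(tmp_path):
    bundle = generate_study(
        ViolationProfile.of("untrimmed_adapters"), 31, tmp_path, n_reads=1000)
    stats = compute_file_stats(bundle, tmp_path / "SYN0001")
    fq = [s for s in stats.values() if s.declared_format == "fastq"]
    for st in fq:
        assert st.adapter_residue_fraction >= 0.30


def test_cohort_generation_counts_and_manifest(tmp_path):
    spec = CohortSpec(
        entries=[(ViolationProfile.of(), 2),
                 (ViolationProfile.of("no_geo", "no_tissue"), 1),
                 (ViolationProfile.of(archive_alignments=False, used_capture=True), 1)],
        seed=3, reads_per_file=300, samples_per_study=2,
    )
    bundles, manifest = generate_cohort(spec, tmp_path / "c1")
    assert len(bundles) == spec.total_studies() == 4
    lines = manifest.read_text().splitlines()
    assert lines[0] == "study_accession\tseed\tplanted_codes"
    assert len(lines) == 5
    assert "no_geo;no_tissue" in lines[3]
    assert "capture" in lines[4] and "no_alignments" in lines[4]
    # same spec + seed -> identical manifest
    _, manifest2 = generate_cohort(spec, tmp_path / "c2")
    assert manifest.read_text() == manifest2.read_text()


def test_under_archive_registers_dataless_samples(tmp_path):
    bundle = generate_study(
        ViolationProfile.of("under_archive(2)"), 31, tmp_path, n_reads=300)
    assert len(bundle.samples) == 5
    assert bundle.paper_report.n_samples_studied_total == 5
    with_runs = {r.sample_accession for r in bundle.runs}
    assert len(with_runs) == 3
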