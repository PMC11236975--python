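"""File inspection: adapter detection, statistics, filter inference,
read-group parsing and alignment validation."""

import math

import numpy as np
import pysam
import pytest

from paleoaudit.archive_model import FileRef
from paleoaudit.seqcheck import (
    SeqFormatError,
    batch_adapter_matches,
    classify_file_role,
    collect_seq_stats,
    detect_adapter_residue,
    infer_hard_filters,
    load_default_adapters,
    parse_read_groups,
    validate_alignment_file,
)

ADAPTER = load_default_adapters()[0][1]  # TruSeq R1


# ---------------------------------------------------------------------------
# adapter detection


def exhaustive_adapter_scan(read, adapters, min_overlap, rate):
    """Independent oracle: check every suffix of the read against every
    adapter prefix, no early exits, no vectorisation."""
    read = read.upper()
    n = len(read)
    for start in range(0, n - min_overlap + 1):
        overlap = n - start
        for _, a in adapters:
            if len(a) < overlap:
                continue
            mism = sum(1 for x, y in zip(read[start:], a[:overlap]) if x != y)
            if mism <= math.floor(rate * overlap):
                return (start, overlap)
    return None


def test_adapter_free_read_has_no_match():
    assert detect_adapter_residue("ACGT" * 8) is None


def test_planted_readthrough_found_at_insert_boundary():
    rng = np.random.default_rng(5)
    insert = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
    read = insert + ADAPTER[:13]
    assert detect_adapter_residue(read, min_overlap=8, max_mismatch_rate=0.1) == (30, 13)


def test_read_shorter_than_min_overlap_returns_none():
    assert detect_adapter_residue("ACGTA", min_overlap=8) is None


def test_mismatch_budget_is_floor_of_rate_times_overlap():
    insert = "ACGT" * 8
    tail = ADAPTER[:20]
    one_off = tail[:10] + ("A" if tail[10] != "A" else "C") + tail[11:]
    # 20-nt overlap allows floor(0.1*20)=2 mismatches
    assert detect_adapter_residue(insert + one_off) == (32, 20)
    three_off = "".join(
        ("A" if c != "A" else "C") if i in (3, 9, 15) else c
        for i, c in enumerate(tail)
    )
    assert detect_adapter_residue(insert + three_off) is None


def test_detector_agrees_with_exhaustive_scan_on_random_reads():
    """Oracle equivalence on 1000 random reads, a third with planted
    read-through, for both the scalar and the vectorised path."""
    rng = np.random.default_rng(42)
    adapters = load_default_adapters()
    reads = []
    for i in range(1000):
        n = int(rng.integers(5, 90))
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, n))
        if i % 3 == 0:
            k = int(rng.integers(4, len(ADAPTER) + 1))
            seq = seq + ADAPTER[:k]
        reads.append(seq)
    expected = [exhaustive_adapter_scan(r, adapters, 8, 0.1) for r in reads]
    got = [detect_adapter_residue(r, adapters, 8, 0.1) for r in reads]
    assert got == expected
    batch = batch_adapter_matches(reads, adapters, 8, 0.1)
    assert list(batch) == [e is not None for e in expected]


# ---------------------------------------------------------------------------
# statistics


def _write_fastq(path, reads):
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def test_fastq_reads_all_count_as_unmapped(tmp_path):
    p = tmp_path / "x.fastq"
    _write_fastq(p, ["ACGTACGTAC"] * 100)
    st = collect_seq_stats(p, n_sample=1000)
    assert st.n_reads_sampled == 100
    assert st.n_unmapped == 100 and st.n_mapped == 0
    assert st.min_mapq_mapped is None
    assert classify_file_role(st) == "raw_reads"


def test_histograms_match_direct_recount(tmp_path):
    rng = np.random.default_rng(3)
    lengths = rng.integers(20, 80, size=500)
    reads = ["".join("ACGT"[b] for b in rng.integers(0, 4, L)) for L in lengths]
    p = tmp_path / "x.fastq"
    _write_fastq(p, reads)
    st = collect_seq_stats(p, n_sample=10_000)
    # brute-force recount from the raw text
    direct = {}
    lines = p.read_text().splitlines()
    for i in range(1, len(lines), 4):
        direct[len(lines[i])] = direct.get(len(lines[i]), 0) + 1
    assert st.length_histogram == direct
    assert st.min_length == min(lengths)
    assert sum(st.length_histogram.values()) == 500


HEADER = {
    "HD": {"VN": "1.6", "SO": "coordinate"},
    "SQ": [{"SN": "ref1", "LN": 1000}, {"SN": "ref2", "LN": 1000}],
    "RG": [{"ID": "rg1", "SM": "S1", "LB": "L1", "PL": "ILLUMINA"}],
}


def _make_record(header, name, seq, tid=0, pos=0, mapq=37, unmapped=False,
                 rg="rg1", flag_extra=0):
    a = pysam.AlignedSegment(pysam.AlignmentHeader.from_dict(header))
    a.query_name = name
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    if unmapped:
        a.flag = 4 | flag_extra
        a.reference_id = -1
        a.reference_start = -1
    else:
        a.flag = flag_extra
        a.reference_id = tid
        a.reference_start = pos
        a.mapping_quality = mapq
        a.cigartuples = [(0, len(seq))]
    if rg is not None:
        a.set_tag("RG", rg, "Z")
    return a


def _write_bam(path, header, records):
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for r in records:
            bam.write(r)


def test_bam_stats_min_mapq_and_roles(tmp_path):
    p = tmp_path / "x.bam"
    recs = [_make_record(HEADER, f"m{i}", "ACGTACGTAC", pos=10 * i, mapq=37)
            for i in range(6)]
    recs += [_make_record(HEADER, f"u{i}", "ACGTACGTAC", unmapped=True)
             for i in range(4)]
    _write_bam(p, HEADER, recs)
    st = collect_seq_stats(p, n_sample=100)
    assert (st.n_mapped, st.n_unmapped) == (6, 4)
    assert st.min_mapq_mapped == 37
    assert st.mapq_histogram == {37: 6}
    assert classify_file_role(st) == "aligned_with_unmapped"
    assert st.distinct_sm_values == {"S1"}


def test_all_unmapped_bam_classifies_as_raw(tmp_path):
    p = tmp_path / "u.bam"
    _write_bam(p, HEADER, [
        _make_record(HEADER, f"u{i}", "ACGT" * 5, unmapped=True) for i in range(5)
    ])
    st = collect_seq_stats(p, n_sample=100)
    assert classify_file_role(st) == "raw_reads"


def test_mapq_255_excluded_from_minimum(tmp_path):
    p = tmp_path / "m.bam"
    _write_bam(p, HEADER, [
        _make_record(HEADER, "a", "ACGTACGT", mapq=255),
        _make_record(HEADER, "b", "ACGTACGT", pos=50, mapq=40),
    ])
    st = collect_seq_stats(p, n_sample=100)
    assert st.min_mapq_mapped == 40


def test_read_groups_parsed_verbatim_and_absent_tags_stay_absent(tmp_path):
    header = dict(HEADER)
    header["RG"] = [{"ID": "rgA", "SM": "S1", "LB": "L1", "PL": "ILLUMINA"},
                    {"ID": "rgB", "SM": "S2"}]
    p = tmp_path / "rg.bam"
    _write_bam(p, header, [_make_record(header, "a", "ACGTACGT", rg="rgA")])
    rgs = parse_read_groups(p)
    assert [(r.rg_id, r.sample_tag, r.library_tag, r.platform_tag) for r in rgs] == [
        ("rgA", "S1", "L1", "ILLUMINA"), ("rgB", "S2", None, None)
    ]
    st = collect_seq_stats(p, n_sample=10)
    assert st.distinct_sm_values == {"S1", "S2"}


def test_header_without_rg_gives_empty_roster(tmp_path):
    header = {"HD": {"VN": "1.6"}, "SQ": HEADER["SQ"]}
    p = tmp_path / "norg.bam"
    _write_bam(p, header, [_make_record(header, "a", "ACGTACGT", rg=None)])
    assert parse_read_groups(p) == []


def test_missing_file_and_bad_format_raise(tmp_path):
    with pytest.raises(FileNotFoundError):
        collect_seq_stats(tmp_path / "absent.fastq")
    bad = tmp_path / "bad.bam"
    bad.write_bytes(b"this is not a BAM file at all")
    with pytest.raises(SeqFormatError):
        collect_seq_stats(bad, n_sample=10)


# ---------------------------------------------------------------------------
# hard-filter inference


def _stats(tmp_path, mapqs, lengths, n_unmapped=0):
    recs = [
        _make_record(HEADER, f"m{i}", "A" * L, pos=i, mapq=q)
        for i, (q, L) in enumerate(zip(mapqs, lengths))
    ]
    recs += [_make_record(HEADER, f"u{i}", "A" * 40, unmapped=True)
             for i in range(n_unmapped)]
    p = tmp_path / "f.bam"
    _write_bam(p, HEADER, recs)
    return collect_seq_stats(p, n_sample=100_000)


def test_high_floor_reads_as_mapq_filter(tmp_path):
    st = _stats(tmp_path, mapqs=[30] * 20, lengths=[40] * 20)
    sig = infer_hard_filters(st, mapq_trigger=25, length_trigger=30, min_confident_n=10)
    assert sig.mapq_filtered and sig.mapq_floor == 30
    assert sig.unmapped_removed


def test_mapq_zero_read_blocks_filter_inference(tmp_path):
    st = _stats(tmp_path, mapqs=[0] + [37] * 19, lengths=[25] + [40] * 19,
                n_unmapped=20)
    sig = infer_hard_filters(st, 25, 30, min_confident_n=10)
    assert not sig.mapq_filtered and sig.mapq_floor is None
    assert not sig.length_filtered
    assert not sig.unmapped_removed
    assert sig.confident


def test_empty_stats_yield_unconfident_all_false(tmp_path):
    st = _stats(tmp_path, mapqs=[], lengths=[], n_unmapped=3)
    sig = infer_hard_filters(st, 25, 30, min_confident_n=10)
    assert not (sig.mapq_filtered or sig.length_filtered or sig.confident)


def test_filter_flags_monotone_nonincreasing_in_trigger(tmp_path):
    st = _stats(tmp_path, mapqs=[25, 30, 37, 60] * 5, lengths=[35, 40, 50, 60] * 5)
    prev_m = prev_l = True
    for trigger in range(0, 80):
        sig = infer_hard_filters(st, trigger, trigger, min_confident_n=10)
        assert prev_m or not sig.mapq_filtered
        assert prev_l or not sig.length_filtered
        prev_m, prev_l = sig.mapq_filtered, sig.length_filtered


# ---------------------------------------------------------------------------
# validation rules


def test_well_formed_bam_passes_validation(tmp_path):
    p = tmp_path / "ok.bam"
    _write_bam(p, HEADER, [
        _make_record(HEADER, "a", "ACGTACGT", pos=5),
        _make_record(HEADER, "b", "ACGTACGT", pos=9),
        _make_record(HEADER, "u", "ACGTACGT", unmapped=True),
    ])
    assert validate_alignment_file(p) == []


def test_undeclared_rg_tag_raises_v3(tmp_path):
    p = tmp_path / "v3.bam"
    _write_bam(p, HEADER, [_make_record(HEADER, "a", "ACGT" * 3, rg="ghost")])
    assert {i.rule_id for i in validate_alignment_file(p)} == {"V3"}


def test_duplicate_rg_ids_raise_v2(tmp_path):
    header = dict(HEADER)
    header["RG"] = [{"ID": "rg1", "SM": "S1"}, {"ID": "rg1", "SM": "S2"}]
    p = tmp_path / "v2.bam"
    _write_bam(p, header, [_make_record(header, "a", "ACGTACGT")])
    assert "V2" in {i.rule_id for i in validate_alignment_file(p)}


def test_unsorted_coordinate_claim_raises_v7(tmp_path):
    p = tmp_path / "v7.bam"
    recs = [_make_record(HEADER, "a", "ACGTACGT", pos=500),
            _make_record(HEADER, "b", "ACGTACGT", pos=100)]
    _write_bam(p, HEADER, recs)
    issues = validate_alignment_file(p)
    assert {i.rule_id for i in issues} == {"V7"}
    # pairwise brute check agrees: positions are genuinely out of order
    with pysam.AlignmentFile(str(p)) as af:
        positions = [r.reference_start for r in af]
    assert any(b < a for a, b in zip(positions, positions[1:]))


def test_missing_hd_line_raises_v1(tmp_path):
    header = {"SQ": HEADER["SQ"], "RG": HEADER["RG"]}
    p = tmp_path / "v1.bam"
    _write_bam(p, header, [_make_record(header, "a", "ACGTACGT")])
    assert "V1" in {i.rule_id for i in validate_alignment_file(p)}


def test_unpaired_record_with_mate_bits_raises_v6(tmp_path):
    p = tmp_path / "v6.bam"
    # 0x8 (mate unmapped) without 0x1 (paired)
    _write_bam(p, HEADER, [_make_record(HEADER, "a", "ACGTACGT", flag_extra=0x8)])
    assert "V6" in {i.rule_id for i in validate_alignment_file(p)}
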