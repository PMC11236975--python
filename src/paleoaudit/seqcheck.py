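"""Content inspection of FASTQ and SAM/BAM files.

Read-level archiving criteria (adapter residue, hard-filter signatures,
unmapped-read removal, read-group completeness, format validity) are decided
on per-file summary statistics.  Sampling is deterministic: the first
``n_sample`` records of a file, mirroring the survey convention of examining
the first listed file of each study, extended to reads.

BAM/CRAM access goes through :mod:`pysam`; FASTQ (plain or gzip) through
``pysam.FastxFile``.  Validation of alignment files uses a fixed internal
rule set (V1–V7) standing in for external validators such as Picard's
ValidateSamFile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pysam

from .archive_model import FileRef

__all__ = [
    "ReadGroupInfo",
    "SeqFileStats",
    "FilterSignature",
    "ValidationIssue",
    "SeqFormatError",
    "load_default_adapters",
    "detect_adapter_residue",
    "batch_adapter_matches",
    "collect_seq_stats",
    "infer_hard_filters",
    "parse_read_groups",
    "validate_alignment_file",
    "classify_file_role",
]

#: MAPQ value meaning "mapping quality unavailable"; excluded from minima
MAPQ_UNAVAILABLE = 255


class SeqFormatError(ValueError):
    """A file could not be read in its declared format.

    Carries the approximate byte offset at which reading failed, when known.
    """

    def __init__(self, message: str, offset: Optional[int] = None):
        super().__init__(message if offset is None else f"{message} (near byte {offset})")
        self.offset = offset


@dataclass(frozen=True)
class ReadGroupInfo:
    """One @RG header line: identifier plus sample/library/platform tags."""

    rg_id: str
    sample_tag: Optional[str] = None   # SM
    library_tag: Optional[str] = None  # LB
    platform_tag: Optional[str] = None  # PL


@dataclass
class SeqFileStats:
    """Summary statistics over the sampled records of one sequence file."""

    declared_format: str
    n_reads_sampled: int
    n_mapped: int
    n_unmapped: int
    min_mapq_mapped: Optional[int]
    mapq_histogram: dict[int, int]
    min_length: Optional[int]
    length_histogram: dict[int, int]
    adapter_residue_fraction: float
    read_groups: list[ReadGroupInfo]
    distinct_sm_values: set[str]
    paired_fraction: float

    def __post_init__(self):
        assert self.n_mapped + self.n_unmapped == self.n_reads_sampled
        assert sum(self.mapq_histogram.values()) == self.n_mapped
        assert sum(self.length_histogram.values()) == self.n_reads_sampled
        assert 0.0 <= self.adapter_residue_fraction <= 1.0
        assert 0.0 <= self.paired_fraction <= 1.0


@dataclass(frozen=True)
class FilterSignature:
    """Inferred evidence that an archived file was hard filtered."""

    unmapped_removed: bool
    mapq_filtered: bool
    mapq_floor: Optional[int]
    length_filtered: bool
    length_floor: Optional[int]
    confident: bool

    def __post_init__(self):
        if not self.mapq_filtered:
            assert self.mapq_floor is None
        if not self.length_filtered:
            assert self.length_floor is None


@dataclass(frozen=True)
class ValidationIssue:
    rule_id: str  # V1..V7
    detail: str
    record_index: Optional[int] = None


# ---------------------------------------------------------------------------
# adapters


def load_default_adapters() -> list[tuple[str, str]]:
    """Shipped adapter set: Illumina TruSeq R1/R2 and Nextera."""
    text = (
        resources.files("paleoaudit").joinpath("data/adapters.fasta").read_text()
    )
    adapters: list[tuple[str, str]] = []
    name, seq = None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                adapters.append((name, "".join(seq)))
            name, seq = line[1:].strip(), []
        elif line.strip():
            seq.append(line.strip().upper())
    if name is not None:
        adapters.append((name, "".join(seq)))
    return adapters


def _adapter_seqs(adapters) -> list[str]:
    if adapters is None:
        adapters = load_default_adapters()
    return [a[1] if isinstance(a, tuple) else a for a in adapters]


def _allowed_mismatches(rate: float, overlap: int) -> int:
    return math.floor(rate * overlap)


def detect_adapter_residue(
    read_sequence: str,
    adapters=None,
    min_overlap: int = 8,
    max_mismatch_rate: float = 0.1,
) -> Optional[tuple[int, int]]:
    """Find 3'-end adapter read-through in a single read.

    Returns ``(start, length)`` for the leftmost (longest) suffix of the read
    matching a prefix of any adapter with overlap >= ``min_overlap`` and at
    most ``floor(max_mismatch_rate * overlap)`` mismatches, or None.
    Non-nucleotide symbols count as mismatches.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not (0.0 <= max_mismatch_rate < 0.5):
        raise ValueError("max_mismatch_rate must be in [0, 0.5)")
    seqs = _adapter_seqs(adapters)
    read = read_sequence.upper()
    n = len(read)
    if n < min_overlap:
        return None
    max_m = max((len(a) for a in seqs), default=0)
    start0 = max(0, n - max_m)
    for start in range(start0, n - min_overlap + 1):
        overlap = n - start
        allowed = _allowed_mismatches(max_mismatch_rate, overlap)
        tail = read[start:]
        for a in seqs:
            if len(a) < overlap:
                continue
            mism = 0
            for x, y in zip(tail, a):
                if x != y:
                    mism += 1
                    if mism > allowed:
                        break
            else:
                return (start, overlap)
    return None


def batch_adapter_matches(
    sequences: Sequence[str],
    adapters=None,
    min_overlap: int = 8,
    max_mismatch_rate: float = 0.1,
) -> np.ndarray:
    """Vectorised any-adapter-match flags for many reads.

    Agrees read-for-read with :func:`detect_adapter_residue` returning a
    match; used to keep per-file statistics fast on large samples.
    """
    seqs = _adapter_seqs(adapters)
    n = len(sequences)
    out = np.zeros(n, dtype=bool)
    if n == 0 or not seqs:
        return out
    max_m = max(len(a) for a in seqs)
    lens = np.array([len(s) for s in sequences], dtype=np.int64)
    # right-align read tails in a fixed-width byte matrix; pad byte 0 never
    # matches a nucleotide, and pad positions are excluded via the length mask
    mat = np.zeros((n, max_m), dtype=np.uint8)
    for i, s in enumerate(sequences):
        tail = s[-max_m:].upper().encode("ascii", errors="replace")
        mat[i, max_m - len(tail):] = np.frombuffer(tail, dtype=np.uint8)
    for a in seqs:
        a_arr = np.frombuffer(a.upper().encode("ascii"), dtype=np.uint8)
        m = len(a_arr)
        for overlap in range(min_overlap, m + 1):
            allowed = _allowed_mismatches(max_mismatch_rate, overlap)
            window = mat[:, max_m - overlap: max_m]
            mism = (window != a_arr[:overlap]).sum(axis=1)
            out |= (mism <= allowed) & (lens >= overlap)
    return out


# ---------------------------------------------------------------------------
# per-file statistics


def _path_of(file: Union[FileRef, str, Path]) -> tuple[str, str]:
    if isinstance(file, FileRef):
        return file.path, file.declared_format
    path = str(file)
    return path, FileRef(path).declared_format


def _fastq_records(path: str, n_sample: int):
    try:
        with pysam.FastxFile(path) as fh:
            for i, rec in enumerate(fh):
                if i >= n_sample:
                    break
                yield rec.sequence or ""
    except OSError as exc:
        raise SeqFormatError(f"cannot read FASTQ {path}: {exc}") from exc


def parse_read_groups(file: Union[FileRef, str, Path]) -> list[ReadGroupInfo]:
    """Read-group roster from a BAM/CRAM header, tags reported verbatim.

    Absent tags stay None; duplicate IDs are preserved in the roster (they
    are flagged as rule V2 by :func:`validate_alignment_file`).
    """
    path, fmt = _path_of(file)
    if fmt not in ("bam", "cram"):
        raise SeqFormatError(f"{path}: read groups require BAM/CRAM, got {fmt}")
    try:
        with pysam.AlignmentFile(path, check_sq=False) as af:
            rgs = af.header.to_dict().get("RG", [])
    except (OSError, ValueError) as exc:
        raise SeqFormatError(f"cannot parse header of {path}: {exc}") from exc
    return [
        ReadGroupInfo(
            rg_id=rg.get("ID", ""),
            sample_tag=rg.get("SM"),
            library_tag=rg.get("LB"),
            platform_tag=rg.get("PL"),
        )
        for rg in rgs
    ]


def collect_seq_stats(
    file: Union[FileRef, str, Path],
    n_sample: int = 10_000,
    adapters=None,
    min_overlap: int = 8,
    max_mismatch_rate: float = 0.1,
) -> SeqFileStats:
    """Summarise the first ``n_sample`` records of a FASTQ or BAM/CRAM file.

    Deterministic (no randomness).  FASTQ reads are all counted as unmapped.
    """
    if n_sample < 1:
        raise ValueError("n_sample must be >= 1")
    path, fmt = _path_of(file)
    if not Path(path).exists():
        raise FileNotFoundError(path)

    sequences: list[str] = []
    length_hist: dict[int, int] = {}
    mapq_hist: dict[int, int] = {}
    n_mapped = 0
    n_unmapped = 0
    n_paired = 0
    read_groups: list[ReadGroupInfo] = []

    if fmt == "fastq":
        for seq in _fastq_records(path, n_sample):
            sequences.append(seq)
            length_hist[len(seq)] = length_hist.get(len(seq), 0) + 1
            n_unmapped += 1
    elif fmt in ("bam", "cram"):
        read_groups = parse_read_groups(file)
        try:
            with pysam.AlignmentFile(path, check_sq=False) as af:
                for i, rec in enumerate(af):
                    if i >= n_sample:
                        break
                    seq = rec.query_sequence or ""
                    sequences.append(seq)
                    length_hist[len(seq)] = length_hist.get(len(seq), 0) + 1
                    if rec.is_unmapped:
                        n_unmapped += 1
                    else:
                        n_mapped += 1
                        mapq_hist[rec.mapping_quality] = (
                            mapq_hist.get(rec.mapping_quality, 0) + 1
                        )
                    if rec.is_paired:
                        n_paired += 1
        except (OSError, ValueError) as exc:
            raise SeqFormatError(f"cannot read alignments in {path}: {exc}") from exc
    else:
        raise SeqFormatError(f"{path}: unsupported format {fmt!r}")

    n_total = n_mapped + n_unmapped
    informative_mapqs = [q for q in mapq_hist if q != MAPQ_UNAVAILABLE]
    matches = batch_adapter_matches(
        sequences, adapters, min_overlap=min_overlap, max_mismatch_rate=max_mismatch_rate
    )
    return SeqFileStats(
        declared_format=fmt,
        n_reads_sampled=n_total,
        n_mapped=n_mapped,
        n_unmapped=n_unmapped,
        min_mapq_mapped=min(informative_mapqs) if informative_mapqs else None,
        mapq_histogram=mapq_hist,
        min_length=min(length_hist) if length_hist else None,
        length_histogram=length_hist,
        adapter_residue_fraction=float(matches.mean()) if n_total else 0.0,
        read_groups=read_groups,
        distinct_sm_values={
            rg.sample_tag for rg in read_groups if rg.sample_tag is not None
        },
        paired_fraction=n_paired / n_total if n_total else 0.0,
    )


def infer_hard_filters(
    stats: SeqFileStats,
    mapq_trigger: int = 25,
    length_trigger: int = 30,
    min_confident_n: int = 1000,
) -> FilterSignature:
    """Infer hard-filter signatures from MAPQ/length distributions.

    A file looks MAPQ-filtered when every mapped read sits at or above the
    trigger threshold; length-filtered when every read is at least the
    length trigger.  Both are only asserted with an adequate sample size
    (``min_confident_n``), since small files can hit floors by chance.
    """
    mapq_filtered = (
        stats.n_mapped >= min_confident_n
        and stats.min_mapq_mapped is not None
        and stats.min_mapq_mapped >= mapq_trigger
    )
    length_filtered = (
        stats.n_reads_sampled >= min_confident_n
        and stats.min_length is not None
        and stats.min_length >= length_trigger
    )
    unmapped_removed = (
        stats.declared_format in ("bam", "cram")
        and stats.n_unmapped == 0
        and stats.n_mapped > 0
    )
    confident = (
        stats.n_mapped >= min_confident_n
        and stats.n_reads_sampled >= min_confident_n
    )
    return FilterSignature(
        unmapped_removed=unmapped_removed,
        mapq_filtered=mapq_filtered,
        mapq_floor=stats.min_mapq_mapped if mapq_filtered else None,
        length_filtered=length_filtered,
        length_floor=stats.min_length if length_filtered else None,
        confident=confident,
    )


def classify_file_role(
    stats: SeqFileStats, declared_format: Optional[str] = None
) -> str:
    """Classify a file as raw reads, alignments, or both.

    FASTQ is raw by definition; an all-unmapped BAM is treated as equivalent
    to FASTQ; a BAM with no unmapped reads carries alignments only; a BAM
    retaining both is aligned-with-unmapped.  Zero sampled reads is
    ambiguous.
    """
    fmt = declared_format or stats.declared_format
    if stats.n_reads_sampled == 0:
        return "ambiguous"
    if fmt == "fastq":
        return "raw_reads"
    if stats.n_mapped == 0:
        return "raw_reads"
    if stats.n_unmapped == 0:
        return "aligned_only"
    return "aligned_with_unmapped"


# ---------------------------------------------------------------------------
# alignment-file validation (fixed rule set V1-V7)


def validate_alignment_file(
    file: Union[FileRef, str, Path], n_sample: int = 10_000
) -> list[ValidationIssue]:
    """Check an alignment file against the fixed validation rules.

    V1 header parses and declares a format version; V2 read-group IDs are
    unique; V3 every record's RG tag references a declared read group; V4
    mapped records have a valid reference and in-bounds position; V5
    sequence and quality strings have equal length; V6 mate/pairing flag
    bits are coherent; V7 records follow the header's declared sort order.
    An empty list means the file passes.
    """
    path, fmt = _path_of(file)
    if fmt not in ("bam", "cram"):
        raise SeqFormatError(f"{path}: validation requires BAM/CRAM, got {fmt}")
    issues: list[ValidationIssue] = []
    try:
        af = pysam.AlignmentFile(path, check_sq=False)
    except (OSError, ValueError) as exc:
        raise SeqFormatError(f"cannot open {path}: {exc}") from exc
    with af:
        header = af.header.to_dict()
        hd = header.get("HD", {})
        if not hd or "VN" not in hd:
            issues.append(
                ValidationIssue("V1", "header lacks an @HD line with a VN field")
            )
        rgs = header.get("RG", [])
        rg_ids = [rg.get("ID", "") for rg in rgs]
        seen: set[str] = set()
        for rid in rg_ids:
            if rid in seen:
                issues.append(ValidationIssue("V2", f"duplicate read group ID {rid!r}"))
            seen.add(rid)
        declared_rgs = set(rg_ids)
        sort_order = hd.get("SO", "unknown")
        lengths = af.lengths
        n_refs = len(lengths)
        prev_key = None
        reported: set[str] = set()
        for i, rec in enumerate(af):
            if i >= n_sample:
                break
            if rec.has_tag("RG"):
                rg = rec.get_tag("RG")
                if rg not in declared_rgs and "V3" not in reported:
                    issues.append(
                        ValidationIssue(
                            "V3", f"record RG tag {rg!r} not declared in header", i
                        )
                    )
                    reported.add("V3")
            if not rec.is_unmapped:
                tid = rec.reference_id
                if tid < 0 or tid >= n_refs:
                    if "V4" not in reported:
                        issues.append(
                            ValidationIssue("V4", f"invalid reference id {tid}", i)
                        )
                        reported.add("V4")
                else:
                    start = rec.reference_start
                    end = rec.reference_end or start
                    if start < 0 or end > lengths[tid]:
                        if "V4" not in reported:
                            issues.append(
                                ValidationIssue(
                                    "V4",
                                    f"position {start}-{end} outside contig bounds",
                                    i,
                                )
                            )
                            reported.add("V4")
            seq = rec.query_sequence
            qual = rec.query_qualities
            if seq is not None and qual is not None and len(seq) != len(qual):
                if "V5" not in reported:
                    issues.append(
                        ValidationIssue(
                            "V5",
                            f"sequence length {len(seq)} != quality length {len(qual)}",
                            i,
                        )
                    )
                    reported.add("V5")
            if not rec.is_paired:
                incoherent = (
                    rec.mate_is_unmapped
                    or rec.is_proper_pair
                    or rec.is_read1
                    or rec.is_read2
                )
                if incoherent and "V6" not in reported:
                    issues.append(
                        ValidationIssue(
                            "V6", "mate/pairing flag bits set on unpaired record", i
                        )
                    )
                    reported.add("V6")
            if sort_order == "coordinate":
                # unmapped reads (no reference) sort after all mapped reads
                tid = rec.reference_id
                key = (
                    (tid, rec.reference_start)
                    if not rec.is_unmapped and tid >= 0
                    else (n_refs, 0)
                )
                if prev_key is not None and key < prev_key and "V7" not in reported:
                    issues.append(
                        ValidationIssue(
                            "V7", "records not in declared coordinate order", i
                        )
                    )
                    reported.add("V7")
                prev_key = key
    return issues
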