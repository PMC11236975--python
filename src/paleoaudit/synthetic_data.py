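"""Seeded generator of synthetic study bundles with planted violations.

Generates complete archived studies — metadata bundle plus FASTQ/BAM files
on disk — whose archiving defects are controlled exactly by a
:class:`ViolationProfile`.  The violation-free baseline passes every
applicable audit criterion; each planted code makes precisely its target
criterion (plus logically entailed composites, recorded in
:data:`ENTAILMENTS`) fail.  That round-trip identity is the module's
central contract and what end-to-end tests assert against.

Reads emulate ancient-DNA shotgun data only in the properties the auditor
inspects: short fragment lengths (triangular 25/45/120 nt), a high
non-endogenous (unmapped) fraction, and a MAPQ mixture with mass at 0.
No damage patterns, duplicates or biological signal are simulated.

Everything is deterministic for a fixed seed: FASTQ output is
byte-identical across runs, BAM record streams are identical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pysam

from .archive_model import (
    AnalysisRecord,
    Attribute,
    FileRef,
    PaperReport,
    RunRecord,
    SampleRecord,
    StudyBundle,
    StudyRecord,
    write_bundle,
)

__all__ = [
    "Violation",
    "ViolationProfile",
    "CohortSpec",
    "ProfileError",
    "VIOLATION_CODES",
    "ENTAILMENTS",
    "simulate_reads",
    "generate_study",
    "generate_cohort",
]


class ProfileError(ValueError):
    pass


#: all recognised violation codes (parameterised ones take an argument)
VIOLATION_CODES = frozenset({
    "aligned_only_no_raw", "untrimmed_adapters", "mapq_filter", "length_filter",
    "strip_unmapped", "no_read_groups", "no_sm", "sm_mismatch", "multi_sm",
    "no_lb", "lb_mismatch", "invalid_bam", "alignments_as_runs",
    "duplicate_sample_suffix", "no_accession_reuse", "no_library_protocol",
    "no_geo", "geo_freetext_only", "no_coords", "no_date", "date_freetext_only",
    "date_no_c14", "no_tissue", "tissue_freetext_only", "no_voucher",
    "no_paper_total", "under_archive",
})

_PARAM_CODES = {"mapq_filter", "length_filter", "invalid_bam", "under_archive"}
_BAM_CODES = {
    "aligned_only_no_raw", "mapq_filter", "length_filter", "strip_unmapped",
    "no_read_groups", "no_sm", "sm_mismatch", "multi_sm", "no_lb",
    "lb_mismatch", "invalid_bam", "alignments_as_runs",
}
_CONTRADICTIONS: tuple[tuple[str, str], ...] = (
    ("no_read_groups", "no_sm"),
    ("no_read_groups", "sm_mismatch"),
    ("no_read_groups", "multi_sm"),
    ("no_read_groups", "no_lb"),
    ("no_read_groups", "lb_mismatch"),
    ("no_read_groups", "invalid_bam"),
    ("no_sm", "sm_mismatch"),
    ("no_sm", "multi_sm"),
    ("no_lb", "lb_mismatch"),
    ("no_geo", "geo_freetext_only"),
    ("no_geo", "no_coords"),
    ("no_date", "date_freetext_only"),
    ("no_date", "date_no_c14"),
    ("no_tissue", "tissue_freetext_only"),
    ("aligned_only_no_raw", "untrimmed_adapters"),
    ("aligned_only_no_raw", "alignments_as_runs"),
    ("aligned_only_no_raw", "duplicate_sample_suffix"),
)


@dataclass(frozen=True)
class Violation:
    """One planted archiving defect, optionally parameterised
    (e.g. ``Violation("mapq_filter", 30)``)."""

    code: str
    param: Optional[Union[int, str]] = None

    def __post_init__(self):
        if self.code not in VIOLATION_CODES:
            raise ProfileError(f"unknown violation code {self.code!r}")
        if self.code in _PARAM_CODES and self.param is None:
            defaults = {"mapq_filter": 30, "length_filter": 35,
                        "invalid_bam": "V3", "under_archive": 1}
            object.__setattr__(self, "param", defaults[self.code])
        if self.code not in _PARAM_CODES and self.param is not None:
            raise ProfileError(f"{self.code} takes no parameter")

    def spec(self) -> str:
        return self.code if self.param is None else f"{self.code}({self.param})"

    @classmethod
    def parse(cls, text: str) -> "Violation":
        m = re.fullmatch(r"(\w+)(?:\(([^)]*)\))?", text.strip())
        if not m:
            raise ProfileError(f"cannot parse violation spec {text!r}")
        code, raw = m.group(1), m.group(2)
        if raw is None:
            return cls(code)
        param: Union[int, str] = int(raw) if raw.isdigit() else raw
        return cls(code, param)


@dataclass(frozen=True)
class ViolationProfile:
    """Ground-truth set of defects to plant into one generated study.

    ``archive_alignments`` / ``used_capture`` select the study design (a
    raw-only study, or a capture study); they are not violations
    themselves but change which criteria apply.
    """

    violations: frozenset[Violation] = frozenset()
    archive_alignments: bool = True
    used_capture: bool = False

    @classmethod
    def of(cls, *codes: Union[str, Violation], archive_alignments: bool = True,
           used_capture: bool = False) -> "ViolationProfile":
        vs = frozenset(
            v if isinstance(v, Violation) else Violation.parse(v) for v in codes
        )
        return cls(vs, archive_alignments, used_capture)

    def codes(self) -> set[str]:
        return {v.code for v in self.violations}

    def get(self, code: str) -> Optional[Violation]:
        for v in self.violations:
            if v.code == code:
                return v
        return None

    def validate(self) -> None:
        codes = self.codes()
        for a, b in _CONTRADICTIONS:
            if a in codes and b in codes:
                raise ProfileError(f"contradictory violation codes: {a} and {b}")
        if not self.archive_alignments:
            bad = codes & _BAM_CODES
            if bad:
                raise ProfileError(
                    f"codes {sorted(bad)} require alignment archiving"
                )


@dataclass
class CohortSpec:
    """A cohort layout: profiles with study counts, one master seed."""

    entries: list[tuple[ViolationProfile, int]]
    seed: int
    reads_per_file: int = 5000
    samples_per_study: int = 3

    def total_studies(self) -> int:
        return sum(n for _, n in self.entries)


#: which criteria each single planted code flips, relative to the
#: violation-free baseline: `fails` = pass->fail, `now_na` = applicable->not,
#: `now_applicable` = not-applicable -> applicable with the given outcome
ENTAILMENTS: dict[str, dict[str, object]] = {
    "aligned_only_no_raw": {
        "fails": {"raw_reads_archived", "both_archived", "alignments_as_analysis"},
        "now_na": {"adapters_trimmed"},
        "now_applicable": {"rawless_unfiltered": True},
    },
    "untrimmed_adapters": {"fails": {"adapters_trimmed"}},
    "mapq_filter": {"fails": {"no_mapq_hardfilter", "no_any_hardfilter"}},
    "length_filter": {"fails": {"no_length_hardfilter", "no_any_hardfilter"}},
    "strip_unmapped": {"fails": set()},
    "no_read_groups": {
        "fails": {"bam_has_rg", "bam_lb_present"},
        "now_na": {"bam_sm_present", "bam_sm_matches", "bam_single_sm",
                   "bam_lb_matches"},
    },
    "no_sm": {
        "fails": {"bam_sm_present"},
        "now_na": {"bam_sm_matches", "bam_single_sm"},
    },
    "sm_mismatch": {"fails": {"bam_sm_matches"}},
    "multi_sm": {"fails": {"bam_single_sm"}},
    "no_lb": {"fails": {"bam_lb_present"}, "now_na": {"bam_lb_matches"}},
    "lb_mismatch": {"fails": {"bam_lb_matches"}},
    "invalid_bam": {"fails": {"bam_valid"}},
    "alignments_as_runs": {"fails": {"alignments_as_analysis"}},
    "duplicate_sample_suffix": {
        "fails": {"libraries_linked_single_sample", "sample_count_match"},
    },
    "no_accession_reuse": {"now_applicable": {"accession_reuse": False}},
    "no_library_protocol": {"fails": {"library_metadata_present"}},
    "no_geo": {"fails": {"geo_any"}, "now_na": {"geo_dedicated", "geo_coords"}},
    "geo_freetext_only": {"fails": {"geo_dedicated", "geo_coords"}},
    "no_coords": {"fails": {"geo_coords"}},
    "no_date": {"fails": {"date_any"}, "now_na": {"date_dedicated", "date_c14"}},
    "date_freetext_only": {"fails": {"date_dedicated"}},
    "date_no_c14": {"fails": {"date_c14"}},
    "no_tissue": {"fails": {"tissue_any"}, "now_na": {"tissue_dedicated"}},
    "tissue_freetext_only": {"fails": {"tissue_dedicated"}},
    "no_voucher": {"fails": {"voucher_present"}},
    "no_paper_total": {"fails": {"total_reported"}},
    "under_archive": {"fails": {"all_samples_archived"}},
}

# ---------------------------------------------------------------------------
# read simulation

_REFS = (("ref1", 50_000), ("ref2", 50_000))
_MAPQ_VALUES = np.array([0, 20, 25, 30, 37, 60])
_MAPQ_WEIGHTS = np.array([0.08, 0.08, 0.09, 0.25, 0.25, 0.25])
_UNMAPPED_FRACTION = 0.7
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"  # TruSeq read-through


def simulate_reads(
    n: int,
    seed: int,
    length_model: tuple[int, int, int] = (25, 45, 120),
) -> list[str]:
    """Deterministic A/C/G/T reads with triangular fragment lengths."""
    if n == 0:
        return []
    lo, mode, hi = length_model
    rng = np.random.default_rng(seed)
    lengths = np.floor(rng.triangular(lo, mode, hi + 1, size=n)).astype(int)
    lengths = np.clip(lengths, lo, hi)
    total = int(lengths.sum())
    flat = _BASES[rng.integers(0, 4, size=total)]
    reads = []
    pos = 0
    for L in lengths:
        reads.append(flat[pos:pos + L].tobytes().decode("ascii"))
        pos += L
    return reads


def _derive_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# metadata construction

_PLACES = ("Norfolk", "Anatolia", "Siberia", "Iberia", "Mongolia", "Caucasus",
           "Scandinavia", "Patagonia", "Levant", "Altai")
_TISSUES = ("petrous bone", "tooth", "rib", "femur", "hair")


def _sample_attributes(profile: ViolationProfile, rng: np.random.Generator) -> list[Attribute]:
    codes = profile.codes()
    place = _PLACES[int(rng.integers(len(_PLACES)))]
    tissue = _TISSUES[int(rng.integers(len(_TISSUES)))]
    age = int(rng.integers(1000, 9000))
    c14 = f"OxA-{int(rng.integers(10_000, 99_999))}"
    lat = float(rng.uniform(-89, 89))
    lon = float(rng.uniform(-179, 179))

    attrs: list[Attribute] = []
    desc_parts: list[str] = []

    if "no_geo" in codes:
        pass
    elif "geo_freetext_only" in codes:
        desc_parts.append(f"Found in {place}")
    else:
        attrs.append(Attribute("geographic location (region and locality)", place))
        if "no_coords" not in codes:
            attrs.append(Attribute("geographic location (latitude)", f"{lat:.4f}"))
            attrs.append(Attribute("geographic location (longitude)", f"{lon:.4f}"))

    date_value = f"{age} BP" if "date_no_c14" in codes else f"{age} BP ({c14})"
    if "no_date" in codes:
        pass
    elif "date_freetext_only" in codes:
        desc_parts.append(f"dated to {date_value}")
    else:
        attrs.append(Attribute("date", date_value))

    if "no_tissue" in codes:
        pass
    elif "tissue_freetext_only" in codes:
        desc_parts.append(tissue.capitalize())
    else:
        attrs.append(Attribute("tissue", tissue))

    if "no_voucher" not in codes:
        attrs.append(
            Attribute("specimen voucher", f"MUS-{int(rng.integers(100, 999))}")
        )
    if desc_parts:
        attrs.append(Attribute("Description", "; ".join(desc_parts)))
    return attrs


# ---------------------------------------------------------------------------
# file fabrication

def _write_fastq(path: Path, reads: Sequence[str], names: Sequence[str]) -> None:
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        for name, seq in zip(names, reads):
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def _plant_adapters(reads: list[str], rng: np.random.Generator,
                    fraction: float = 0.4) -> list[str]:
    """Append adapter read-through (>=10 nt) to a fraction of reads."""
    out = []
    for seq in reads:
        if rng.random() < fraction:
            k = int(rng.integers(10, len(_ADAPTER) + 1))
            out.append(seq + _ADAPTER[:k])
        else:
            out.append(seq)
    return out


def _build_bam(
    path: Path,
    reads: Sequence[str],
    rng: np.random.Generator,
    profile: ViolationProfile,
    sample_alias: str,
    sample_accession: str,
    library_name: str,
) -> None:
    codes = profile.codes()
    n = len(reads)
    reads = list(reads)
    mapped = rng.random(n) >= _UNMAPPED_FRACTION
    tids = rng.integers(0, len(_REFS), size=n)
    positions = np.array([
        int(rng.integers(0, _REFS[t][1] - len(reads[i]) - 1))
        for i, t in enumerate(tids)
    ])
    mapqs = rng.choice(_MAPQ_VALUES, size=n, p=_MAPQ_WEIGHTS)

    keep = np.ones(n, dtype=bool)
    v = profile.get("mapq_filter")
    if v is not None:
        keep &= ~mapped | (mapqs >= int(v.param))
    v = profile.get("length_filter")
    if v is not None:
        lens = np.array([len(s) for s in reads])
        keep &= lens >= int(v.param)
    if "strip_unmapped" in codes or "aligned_only_no_raw" in codes:
        keep &= mapped

    # an unfiltered ancient-DNA file always contains multi-mapping (MAPQ 0)
    # and sub-threshold-length reads; guarantee that signature regardless of
    # file size whenever the corresponding filter is not planted, so the
    # baseline's appearance does not depend on sampling luck in tiny files
    kept_mapped = [i for i in range(n) if keep[i] and mapped[i]]
    if kept_mapped:
        if "mapq_filter" not in codes:
            mapqs[kept_mapped[0]] = 0
        if "length_filter" not in codes:
            j = kept_mapped[-1]
            reads[j] = reads[j][:26]

    rg_id = f"{sample_alias}.{library_name}"
    read_groups: list[dict] = []
    if "no_read_groups" not in codes:
        rg = {"ID": rg_id, "PL": "ILLUMINA"}
        if "no_sm" not in codes:
            rg["SM"] = (
                f"XQ-{sample_alias}-wrong" if "sm_mismatch" in codes else sample_alias
            )
        if "no_lb" not in codes:
            rg["LB"] = (
                f"{library_name}-wrong" if "lb_mismatch" in codes else library_name
            )
        read_groups.append(rg)
        if "multi_sm" in codes:
            # second read group names the same sample by accession: both SM
            # values resolve in the archive metadata, but one file now
            # carries two sample names
            rg2 = dict(rg)
            rg2["ID"] = rg_id + ".b"
            rg2["SM"] = sample_accession
            read_groups.append(rg2)

    invalid = profile.get("invalid_bam")
    invalid_rule = str(invalid.param) if invalid is not None else None

    header: dict = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in _REFS],
    }
    if invalid_rule == "V1":
        del header["HD"]
    if read_groups:
        header["RG"] = read_groups

    order = np.arange(n)[keep]
    mapped_idx = sorted(
        (i for i in order if mapped[i]),
        key=lambda i: (int(tids[i]), int(positions[i])),
        reverse=(invalid_rule == "V7"),
    )
    unmapped_idx = [i for i in order if not mapped[i]]

    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for out_i, i in enumerate(mapped_idx + unmapped_idx):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"r{i}"
            a.query_sequence = reads[i]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(reads[i]))
            if mapped[i]:
                a.flag = 0
                a.reference_id = int(tids[i])
                a.reference_start = int(positions[i])
                a.mapping_quality = int(mapqs[i])
                a.cigartuples = [(0, len(reads[i]))]
            else:
                a.flag = 4
                a.reference_id = -1
                a.reference_start = -1
                a.mapping_quality = 0
            if read_groups:
                if invalid_rule == "V3" and out_i % 97 == 0:
                    a.set_tag("RG", "undeclared-rg", "Z")
                elif len(read_groups) > 1:
                    a.set_tag("RG", read_groups[out_i % len(read_groups)]["ID"], "Z")
                else:
                    a.set_tag("RG", rg_id, "Z")
            bam.write(a)


# ---------------------------------------------------------------------------
# study and cohort generation

_PROTOCOL_TEXT = "double-stranded library preparation, half-UDG treatment"


def generate_study(
    profile: ViolationProfile,
    seed: int,
    out_dir: Union[str, Path],
    accession: str = "SYN0001",
    n_samples: int = 3,
    n_reads: int = 5000,
) -> StudyBundle:
    """Generate one synthetic study: metadata bundle plus data files.

    Files are written under ``out_dir/<accession>/`` with paths stored
    relative to that directory; the canonical bundle goes to
    ``bundle.json`` alongside them.  FASTQ output is byte-deterministic
    for a fixed seed.
    """
    profile.validate()
    codes = profile.codes()
    study_dir = Path(out_dir) / accession
    study_dir.mkdir(parents=True, exist_ok=True)

    samples: list[SampleRecord] = []
    runs: list[RunRecord] = []
    analyses: list[AnalysisRecord] = []

    aligned_only = "aligned_only_no_raw" in codes
    protocol = None if "no_library_protocol" in codes else _PROTOCOL_TEXT

    for i in range(1, n_samples + 1):
        meta_rng = _derive_rng(seed, i, 0)
        s_acc = f"{accession}-SAM{i}"
        alias = f"{accession}_IND{i}"
        sample = SampleRecord(
            accession=s_acc,
            alias=alias,
            title=f"Ancient individual {i}",
            attributes=_sample_attributes(profile, meta_rng),
        )
        samples.append(sample)
        library = f"LIB{i}"

        if not aligned_only:
            fq_name = f"{s_acc}.fastq"
            reads = simulate_reads(n_reads, int(_derive_rng(seed, i, 1).integers(2**31)))
            if "untrimmed_adapters" in codes:
                reads = _plant_adapters(reads, _derive_rng(seed, i, 2))
            _write_fastq(study_dir / fq_name, reads, [f"r{j}" for j in range(len(reads))])
            runs.append(RunRecord(
                accession=f"{accession}-RUN{i}",
                sample_accession=s_acc,
                library_name=library,
                library_construction_protocol=protocol,
                instrument_platform="ILLUMINA",
                submitted_format="FASTQ",
                files=[FileRef(fq_name, "fastq")],
            ))

        if profile.archive_alignments:
            bam_name = f"{s_acc}.bam"
            bam_reads = simulate_reads(
                n_reads, int(_derive_rng(seed, i, 3).integers(2**31))
            )
            _build_bam(
                study_dir / bam_name, bam_reads, _derive_rng(seed, i, 4),
                profile, alias, s_acc, library,
            )
            as_run = aligned_only or "alignments_as_runs" in codes
            if as_run:
                runs.append(RunRecord(
                    accession=f"{accession}-BRUN{i}",
                    sample_accession=s_acc,
                    library_name=library,
                    library_construction_protocol=protocol,
                    instrument_platform="ILLUMINA",
                    submitted_format="BAM",
                    files=[FileRef(bam_name, "bam")],
                ))
            else:
                analyses.append(AnalysisRecord(
                    accession=f"{accession}-ANA{i}",
                    analysis_type="REFERENCE_ALIGNMENT",
                    linked_run_accessions=(
                        [f"{accession}-RUN{i}"] if not aligned_only else []
                    ),
                    linked_sample_accessions=[s_acc],
                    files=[FileRef(bam_name, "bam")],
                ))

    if "duplicate_sample_suffix" in codes:
        # the first sample registered a second time under a suffixed alias,
        # with its own library and data — an informal duplicate
        meta_rng = _derive_rng(seed, n_samples + 1, 0)
        d_acc = f"{accession}-SAMD1"
        dup = SampleRecord(
            accession=d_acc,
            alias=f"{accession}_IND1_new",
            title="Ancient individual 1 (additional data)",
            attributes=_sample_attributes(profile, meta_rng),
        )
        samples.append(dup)
        fq_name = f"{d_acc}.fastq"
        reads = simulate_reads(
            n_reads, int(_derive_rng(seed, n_samples + 1, 1).integers(2**31))
        )
        if "untrimmed_adapters" in codes:
            reads = _plant_adapters(reads, _derive_rng(seed, n_samples + 1, 2))
        _write_fastq(study_dir / fq_name, reads, [f"r{j}" for j in range(len(reads))])
        runs.append(RunRecord(
            accession=f"{accession}-RUND1",
            sample_accession=d_acc,
            library_name="LIB1b",
            library_construction_protocol=protocol,
            instrument_platform="ILLUMINA",
            submitted_format="FASTQ",
            files=[FileRef(fq_name, "fastq")],
        ))

    studied_total = n_samples
    v = profile.get("under_archive")
    if v is not None:
        # k studied samples were registered but their data never archived
        k = int(v.param)
        studied_total = n_samples + k
        for j in range(1, k + 1):
            meta_rng = _derive_rng(seed, n_samples + 10 + j, 0)
            samples.append(SampleRecord(
                accession=f"{accession}-SAMX{j}",
                alias=f"{accession}_INDX{j}",
                title=f"Screened individual {j} (no data archived)",
                attributes=_sample_attributes(profile, meta_rng),
            ))

    previously_published: list[tuple[str, str]] = []
    if "no_accession_reuse" in codes:
        # paper declares sample 1 as previously published elsewhere, but the
        # bundle registered a fresh accession instead of reusing the old one
        previously_published.append((samples[0].alias, "EXT-PREV-0001"))

    report = PaperReport(
        n_samples_analysed=n_samples,
        n_samples_studied_total=studied_total,
        used_capture=profile.used_capture,
        previously_published_samples=previously_published,
        total_reported_in_paper="no_paper_total" not in codes,
    )
    bundle = StudyBundle(
        study=StudyRecord(
            accession=accession,
            title=f"Synthetic ancient genomics study {accession}",
            description="Synthetic study generated with planted archiving defects",
        ),
        samples=samples,
        runs=runs,
        analyses=analyses,
        paper_report=report,
    )
    write_bundle(bundle, study_dir / "bundle.json")
    return bundle


def generate_cohort(
    spec: CohortSpec, out_dir: Union[str, Path]
) -> tuple[list[StudyBundle], Path]:
    """Generate every study of a cohort spec; returns bundles + manifest.

    Per-study seeds are ``spec.seed + study_index``; the manifest TSV
    records the ground-truth profile per study accession.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundles: list[StudyBundle] = []
    manifest_rows = ["study_accession\tseed\tplanted_codes"]
    idx = 0
    for profile, n_studies in spec.entries:
        if n_studies < 1:
            raise ProfileError("n_studies must be >= 1 for every entry")
        profile.validate()
        for _ in range(n_studies):
            idx += 1
            accession = f"SYN{idx:04d}"
            bundle = generate_study(
                profile,
                seed=spec.seed + idx,
                out_dir=out,
                accession=accession,
                n_samples=spec.samples_per_study,
                n_reads=spec.reads_per_file,
            )
            bundles.append(bundle)
            tags = sorted(v.spec() for v in profile.violations)
            if not profile.archive_alignments:
                tags.append("no_alignments")
            if profile.used_capture:
                tags.append("capture")
            manifest_rows.append(
                f"{accession}\t{spec.seed + idx}\t{';'.join(tags) or '-'}"
            )
    manifest_path = out / "manifest.tsv"
    manifest_path.write_text("\n".join(manifest_rows) + "\n", encoding="utf-8")
    return bundles, manifest_path
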