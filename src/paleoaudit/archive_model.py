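"""INSDC-like domain model for archived sequencing studies.

The public sequence archives (ENA/SRA/DDBJ plus the BioProject and BioSample
databases) organise data as studies, samples, sequencing runs and secondary
analysis files.  This module provides a minimal, offline representation of
that hierarchy — a :class:`StudyBundle` — together with readers and writers
for a canonical JSON serialisation and adapters for the two archive export
dialects commonly obtained from local disk: the ENA filereport TSV and
BioSample attribute dumps.

All readers validate referential integrity (every run must point at a sample
present in the bundle, every analysis link must resolve) and reject broken
bundles rather than repairing them silently.
"""

from __future__ import annotations

import csv
import io
import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "Attribute",
    "StudyRecord",
    "SampleRecord",
    "RunRecord",
    "AnalysisRecord",
    "FileRef",
    "PaperReport",
    "StudyBundle",
    "BundleParseError",
    "BundleIntegrityError",
    "load_bundle",
    "write_bundle",
    "from_ena_filereport",
]


class BundleParseError(ValueError):
    """The on-disk document does not conform to the bundle schema."""


class BundleIntegrityError(ValueError):
    """Records in the bundle reference accessions that do not resolve."""


_FORMATS = {"fastq", "bam", "cram", "other"}
_EXT_FORMAT = {
    ".fastq": "fastq",
    ".fq": "fastq",
    ".fastq.gz": "fastq",
    ".fq.gz": "fastq",
    ".bam": "bam",
    ".cram": "cram",
    ".sam": "bam",
}


def _format_from_path(path: str) -> str:
    name = path.lower()
    for ext, fmt in _EXT_FORMAT.items():
        if name.endswith(ext):
            return fmt
    return "other"


@dataclass(frozen=True)
class Attribute:
    """One free-form tag/value pair, as used by BioSample and ENA metadata.

    Tags are preserved verbatim (case and spacing); matching against
    vocabulary lists is done case-insensitively by consumers.
    """

    tag: str
    value: str
    units: Optional[str] = None


@dataclass(frozen=True)
class FileRef:
    """Reference to a data file on local disk with its declared format."""

    path: str
    declared_format: str = ""

    def __post_init__(self):
        fmt = self.declared_format or _format_from_path(self.path)
        if fmt not in _FORMATS:
            raise BundleParseError(
                f"FileRef.declared_format must be one of {sorted(_FORMATS)}, got {fmt!r}"
            )
        object.__setattr__(self, "declared_format", fmt)


@dataclass
class StudyRecord:
    accession: str
    title: str = ""
    description: str = ""

    def __post_init__(self):
        if not self.accession:
            raise BundleParseError("study accession must be non-empty")


@dataclass
class SampleRecord:
    accession: str
    alias: str = ""
    title: str = ""
    attributes: list[Attribute] = field(default_factory=list)

    def __post_init__(self):
        if not self.accession:
            raise BundleParseError("sample accession must be non-empty")

    def attribute(self, tag: str) -> Optional[Attribute]:
        """First attribute whose tag matches case-insensitively, else None."""
        needle = tag.strip().lower()
        for a in self.attributes:
            if a.tag.strip().lower() == needle:
                return a
        return None


@dataclass
class RunRecord:
    accession: str
    sample_accession: str
    library_name: str = ""
    library_construction_protocol: Optional[str] = None
    instrument_platform: str = ""
    submitted_format: str = ""
    files: list[FileRef] = field(default_factory=list)
    attributes: list[Attribute] = field(default_factory=list)

    def __post_init__(self):
        if not self.accession:
            raise BundleParseError("run accession must be non-empty")


@dataclass
class AnalysisRecord:
    accession: str
    analysis_type: str = "SEQUENCE_ASSEMBLY"
    linked_run_accessions: list[str] = field(default_factory=list)
    linked_sample_accessions: list[str] = field(default_factory=list)
    files: list[FileRef] = field(default_factory=list)

    def __post_init__(self):
        if not self.accession:
            raise BundleParseError("analysis accession must be non-empty")


@dataclass
class PaperReport:
    """Author-declared facts, transcribed from the publication.

    These are the denominators against which archive contents are compared:
    how many samples the paper analysed, how many it studied in total
    (including screening negatives), whether target capture was used, and
    which samples were declared as previously published elsewhere.
    """

    n_samples_analysed: Optional[int] = None
    n_samples_studied_total: Optional[int] = None
    used_capture: bool = False
    previously_published_samples: list[tuple[str, str]] = field(default_factory=list)
    total_reported_in_paper: bool = False

    def __post_init__(self):
        for name in ("n_samples_analysed", "n_samples_studied_total"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise BundleParseError(f"{name} must be non-negative")
        if (
            self.n_samples_analysed is not None
            and self.n_samples_studied_total is not None
            and self.n_samples_studied_total < self.n_samples_analysed
        ):
            raise BundleParseError(
                "n_samples_studied_total must be >= n_samples_analysed"
            )
        self.previously_published_samples = [
            tuple(p) for p in self.previously_published_samples
        ]


@dataclass
class StudyBundle:
    """One archived study with all its linked records."""

    study: StudyRecord
    samples: list[SampleRecord] = field(default_factory=list)
    runs: list[RunRecord] = field(default_factory=list)
    analyses: list[AnalysisRecord] = field(default_factory=list)
    paper_report: Optional[PaperReport] = None

    def sample_by_accession(self, accession: str) -> SampleRecord:
        for s in self.samples:
            if s.accession == accession:
                return s
        raise KeyError(accession)

    def runs_for_sample(self, sample_accession: str) -> list[RunRecord]:
        return [r for r in self.runs if r.sample_accession == sample_accession]

    def all_files(self) -> list[FileRef]:
        out: list[FileRef] = []
        for r in self.runs:
            out.extend(r.files)
        for a in self.analyses:
            out.extend(a.files)
        return out

    def validate(self) -> None:
        """Raise :class:`BundleIntegrityError` on any dangling reference."""
        sample_accs = [s.accession for s in self.samples]
        dupes = {a for a in sample_accs if sample_accs.count(a) > 1}
        if dupes:
            raise BundleIntegrityError(
                f"duplicate sample accessions in bundle: {sorted(dupes)}"
            )
        known = set(sample_accs)
        run_accs = set()
        for r in self.runs:
            if r.accession in run_accs:
                raise BundleIntegrityError(f"duplicate run accession {r.accession}")
            run_accs.add(r.accession)
            if r.sample_accession not in known:
                raise BundleIntegrityError(
                    f"run {r.accession} references unknown sample "
                    f"{r.sample_accession!r}"
                )
        for a in self.analyses:
            for s in a.linked_sample_accessions:
                if s not in known:
                    raise BundleIntegrityError(
                        f"analysis {a.accession} references unknown sample {s!r}"
                    )
            for r in a.linked_run_accessions:
                if r not in run_accs:
                    raise BundleIntegrityError(
                        f"analysis {a.accession} references unknown run {r!r}"
                    )


# ---------------------------------------------------------------------------
# canonical JSON serialisation


def _attr_to_dict(a: Attribute) -> dict:
    d = {"tag": a.tag, "value": a.value}
    if a.units is not None:
        d["units"] = a.units
    return d


def _file_to_dict(f: FileRef) -> dict:
    return {"path": f.path, "declared_format": f.declared_format}


def bundle_to_dict(bundle: StudyBundle) -> dict:
    """Canonical plain-dict form of a bundle (stable key order)."""
    doc: dict = {
        "study": {
            "accession": bundle.study.accession,
            "title": bundle.study.title,
            "description": bundle.study.description,
        },
        "samples": [
            {
                "accession": s.accession,
                "alias": s.alias,
                "title": s.title,
                "attributes": [_attr_to_dict(a) for a in s.attributes],
            }
            for s in bundle.samples
        ],
        "runs": [
            {
                "accession": r.accession,
                "sample_accession": r.sample_accession,
                "library_name": r.library_name,
                "library_construction_protocol": r.library_construction_protocol,
                "instrument_platform": r.instrument_platform,
                "submitted_format": r.submitted_format,
                "files": [_file_to_dict(f) for f in r.files],
                "attributes": [_attr_to_dict(a) for a in r.attributes],
            }
            for r in bundle.runs
        ],
        "analyses": [
            {
                "accession": a.accession,
                "analysis_type": a.analysis_type,
                "linked_run_accessions": list(a.linked_run_accessions),
                "linked_sample_accessions": list(a.linked_sample_accessions),
                "files": [_file_to_dict(f) for f in a.files],
            }
            for a in bundle.analyses
        ],
        "paper_report": None,
    }
    if bundle.paper_report is not None:
        pr = bundle.paper_report
        doc["paper_report"] = {
            "n_samples_analysed": pr.n_samples_analysed,
            "n_samples_studied_total": pr.n_samples_studied_total,
            "used_capture": pr.used_capture,
            "previously_published_samples": [
                list(p) for p in pr.previously_published_samples
            ],
            "total_reported_in_paper": pr.total_reported_in_paper,
        }
    return doc


def _require(d: dict, key: str, ctx: str):
    if key not in d:
        raise BundleParseError(f"missing field {key!r} in {ctx}")
    return d[key]


def bundle_from_dict(doc: dict) -> StudyBundle:
    if not isinstance(doc, dict):
        raise BundleParseError("bundle document must be a JSON object")
    study_d = _require(doc, "study", "bundle")
    study = StudyRecord(
        accession=_require(study_d, "accession", "study"),
        title=study_d.get("title", ""),
        description=study_d.get("description", ""),
    )
    samples = [
        SampleRecord(
            accession=_require(s, "accession", "sample"),
            alias=s.get("alias", ""),
            title=s.get("title", ""),
            attributes=[
                Attribute(
                    _require(a, "tag", "attribute"),
                    _require(a, "value", "attribute"),
                    a.get("units"),
                )
                for a in s.get("attributes", [])
            ],
        )
        for s in doc.get("samples", [])
    ]
    runs = [
        RunRecord(
            accession=_require(r, "accession", "run"),
            sample_accession=_require(r, "sample_accession", "run"),
            library_name=r.get("library_name", ""),
            library_construction_protocol=r.get("library_construction_protocol"),
            instrument_platform=r.get("instrument_platform", ""),
            submitted_format=r.get("submitted_format", ""),
            files=[
                FileRef(_require(f, "path", "file"), f.get("declared_format", ""))
                for f in r.get("files", [])
            ],
            attributes=[
                Attribute(a["tag"], a["value"], a.get("units"))
                for a in r.get("attributes", [])
            ],
        )
        for r in doc.get("runs", [])
    ]
    analyses = [
        AnalysisRecord(
            accession=_require(a, "accession", "analysis"),
            analysis_type=a.get("analysis_type", ""),
            linked_run_accessions=list(a.get("linked_run_accessions", [])),
            linked_sample_accessions=list(a.get("linked_sample_accessions", [])),
            files=[
                FileRef(_require(f, "path", "file"), f.get("declared_format", ""))
                for f in a.get("files", [])
            ],
        )
        for a in doc.get("analyses", [])
    ]
    pr_d = doc.get("paper_report")
    paper_report = None
    if pr_d is not None:
        paper_report = PaperReport(
            n_samples_analysed=pr_d.get("n_samples_analysed"),
            n_samples_studied_total=pr_d.get("n_samples_studied_total"),
            used_capture=bool(pr_d.get("used_capture", False)),
            previously_published_samples=[
                tuple(p) for p in pr_d.get("previously_published_samples", [])
            ],
            total_reported_in_paper=bool(pr_d.get("total_reported_in_paper", False)),
        )
    bundle = StudyBundle(
        study=study,
        samples=samples,
        runs=runs,
        analyses=analyses,
        paper_report=paper_report,
    )
    bundle.validate()
    return bundle


def load_bundle(path: Union[str, Path]) -> StudyBundle:
    """Load and validate a canonical JSON study bundle."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise BundleParseError(f"invalid JSON in {path}: {exc}") from exc
    return bundle_from_dict(doc)


def write_bundle(bundle: StudyBundle, path: Union[str, Path]) -> None:
    """Serialise a bundle canonically (deterministic byte output).

    Bundles failing their own invariants are refused.
    """
    bundle.validate()
    text = json.dumps(bundle_to_dict(bundle), indent=1, sort_keys=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
        fh.write("\n")


# ---------------------------------------------------------------------------
# archive-export adapters

#: columns an ENA filereport must carry for the adapter to work
ENA_MANDATORY_COLUMNS = ("run_accession", "sample_accession")
_ENA_KNOWN = {
    "run_accession",
    "sample_accession",
    "library_name",
    "library_construction_protocol",
    "instrument_platform",
    "submitted_format",
    "fastq_ftp",
    "submitted_ftp",
    "sample_alias",
    "sample_title",
    "study_accession",
    "study_title",
}


def _split_ftp_field(value: str) -> list[str]:
    return [v for v in value.split(";") if v]


def from_ena_filereport(
    report_path: Union[str, Path],
    attributes_path: Optional[Union[str, Path]] = None,
) -> StudyBundle:
    """Build a bundle from an ENA filereport TSV plus optional BioSample dump.

    One :class:`RunRecord` is created per data row.  File columns
    (``fastq_ftp`` / ``submitted_ftp``) are recorded as references but never
    fetched.  Unrecognised columns are preserved as run attributes.

    ``attributes_path`` may point at a TSV with columns
    ``sample_accession, tag, value[, units]`` or a JSON list of objects with
    those keys; the attributes are attached to the matching samples.
    """
    with open(report_path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise BundleParseError(f"{report_path}: empty filereport (no header)")
        missing = [c for c in ENA_MANDATORY_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise BundleParseError(
                f"{report_path}: missing mandatory columns {missing}; "
                f"expected at least {list(ENA_MANDATORY_COLUMNS)}"
            )
        rows = list(reader)

    study_acc = ""
    study_title = ""
    samples: dict[str, SampleRecord] = {}
    runs: list[RunRecord] = []
    for row in rows:
        row = {k: (v or "") for k, v in row.items() if k is not None}
        study_acc = study_acc or row.get("study_accession", "")
        study_title = study_title or row.get("study_title", "")
        s_acc = row["sample_accession"]
        if s_acc and s_acc not in samples:
            samples[s_acc] = SampleRecord(
                accession=s_acc,
                alias=row.get("sample_alias", ""),
                title=row.get("sample_title", ""),
            )
        files = []
        fmt_hint = row.get("submitted_format", "").strip().lower()
        for col in ("fastq_ftp", "submitted_ftp"):
            for p in _split_ftp_field(row.get(col, "")):
                declared = ""
                if col == "fastq_ftp":
                    declared = "fastq"
                elif fmt_hint in _FORMATS:
                    declared = fmt_hint
                files.append(FileRef(p, declared))
        extra = [
            Attribute(k, v)
            for k, v in row.items()
            if k not in _ENA_KNOWN and v
        ]
        runs.append(
            RunRecord(
                accession=row["run_accession"],
                sample_accession=s_acc,
                library_name=row.get("library_name", ""),
                library_construction_protocol=row.get(
                    "library_construction_protocol"
                )
                or None,
                instrument_platform=row.get("instrument_platform", ""),
                submitted_format=row.get("submitted_format", ""),
                files=files,
                attributes=extra,
            )
        )

    if attributes_path is not None:
        _attach_biosample_attributes(samples, attributes_path)

    bundle = StudyBundle(
        study=StudyRecord(accession=study_acc or "UNKNOWN", title=study_title),
        samples=list(samples.values()),
        runs=runs,
    )
    bundle.validate()
    return bundle


def _attach_biosample_attributes(
    samples: dict[str, SampleRecord], path: Union[str, Path]
) -> None:
    text = Path(path).read_text(encoding="utf-8")
    entries: list[dict]
    if text.lstrip().startswith("["):
        entries = json.loads(text)
    else:
        reader = csv.DictReader(io.StringIO(text), delimiter="\t")
        if reader.fieldnames is None or "sample_accession" not in reader.fieldnames:
            raise BundleParseError(
                f"{path}: BioSample attribute table needs a sample_accession column"
            )
        entries = list(reader)
    for e in entries:
        acc = e.get("sample_accession", "")
        if acc not in samples:
            continue
        samples[acc].attributes.append(
            Attribute(e["tag"], e.get("value", ""), e.get("units") or None)
        )
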