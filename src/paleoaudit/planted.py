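"""Planted survey cohorts: turn per-criterion marginal counts into
generator specs, and audit whole generated cohorts.

The fixture files ``fixtures/table*.json`` transcribe how many studies met
each criterion in the published survey.  The builders here construct
:class:`~paleoaudit.synthetic_data.CohortSpec` layouts that plant exactly
those marginals, so that an end-to-end audit of the generated cohort must
recover the printed pass counts from the files and metadata alone.

Only per-table marginals are encoded; the true joint per-study profile
across all criteria is not public, so each builder targets one criterion
family at a time.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Union

from .cli_report import audit_study
from .cohort import CohortSummary, aggregate
from .config import AuditConfig
from .synthetic_data import CohortSpec, ViolationProfile, generate_cohort

__all__ = [
    "load_table_counts",
    "raw_archiving_cohort",
    "adapter_trimming_cohort",
    "joint_archiving_cohort",
    "analysis_registration_cohort",
    "mapq_filtering_cohort",
    "length_filtering_cohort",
    "sample_count_cohort",
    "read_group_cohort",
    "sm_matching_cohort",
    "geography_cohort",
    "archival_completeness_cohort",
    "generate_and_audit",
]

Counts = Mapping[str, tuple[int, int]]


def load_table_counts(fixtures_dir: Union[str, Path]) -> dict[str, tuple[int, int]]:
    """Merge all ``table*.json`` fixtures into criterion -> (n_pass, n_applicable)."""
    out: dict[str, tuple[int, int]] = {}
    for path in sorted(Path(fixtures_dir).glob("table*.json")):
        doc = json.loads(path.read_text(encoding="utf-8"))
        for cid, c in doc["criteria"].items():
            out[cid] = (int(c["n_pass"]), int(c["n_applicable"]))
    return out


def _spec(entries, seed, reads):
    return CohortSpec(entries=entries, seed=seed, reads_per_file=reads)


def raw_archiving_cohort(counts: Counts, seed: int, reads: int = 5000) -> CohortSpec:
    """Full-size cohort splitting raw-read archivers from aligned-only studies."""
    n_pass, n_total = counts["raw_reads_archived"]
    return _spec([
        (ViolationProfile.of(), n_pass),
        (ViolationProfile.of("aligned_only_no_raw"), n_total - n_pass),
    ], seed, reads)


def adapter_trimming_cohort(counts: Counts, seed: int, reads: int = 5000) -> CohortSpec:
    """Raw-archiving studies, a subset with adapter read-through planted."""
    n_pass, n_total = counts["adapters_trimmed"]
    return _spec([
        (ViolationProfile.of(), n_pass),
        (ViolationProfile.of("untrimmed_adapters"), n_total - n_pass),
    ], seed, reads)


def joint_archiving_cohort(counts: Counts, seed: int, reads: int = 5000) -> CohortSpec:
    """Both-archiving, raw-only and aligned-only studies in the joint split
    implied by the raw/alignments/both marginals."""
    n_raw, n_total = counts["raw_reads_archived"]
    n_aln, _ = counts["alignments_archived"]
    n_both, _ = counts["both_archived"]
    raw_only = n_raw - n_both
    aligned_only = n_aln - n_both
    assert n_both + raw_only + aligned_only == n_total, "marginals leave empty studies"
    return _spec([
        (ViolationProfile.of(), n_both),
        (ViolationProfile.of(archive_alignments=False), raw_only),
        (ViolationProfile.of("aligned_only_no_raw"), aligned_only),
    ], seed, reads)


def analysis_registration_cohort(counts: Counts, seed: int, reads: int = 5000) -> CohortSpec:
    """Alignment-archiving studies; most register BAMs as runs, not analyses."""
    n_pass, n_total = counts["alignments_as_analysis"]
    return _spec([
        (ViolationProfile.of(), n_pass),
        (ViolationProfile.of("alignments_as_runs"), n_total - n_pass),
    ], seed, reads)


def mapq_filtering_cohort(counts: Counts, seed: int, reads: int = 5000) -> CohortSpec:
    """Alignment-archiving studies, a subset hard filtered at MAPQ >= 30."""
    n_pass, n_total = counts["no_mapq_hardfilter"]
    return _spec([
        (ViolationProfile.of(), n_pass),
        (ViolationProfile.of("mapq_filter(30)"), n_total - n_pass),
    ], seed, reads)


def length_filtering_cohort(counts: Counts, seed: int, reads: int = 5000) -> CohortSpec:
    """Alignment-archiving studies, a subset hard filtered at length >= 35."""
    n_pass, n_total = counts["no_length_hardfilter"]
    return _spec([
        (ViolationProfile.of(), n_pass),
        (ViolationProfile.of("length_filter(35)"), n_total - n_pass),
    ], seed, reads)


def sample_count_cohort(counts: Counts, seed: int, reads: int = 5000) -> CohortSpec:
    """Studies declaring their analysed-sample count, a subset with
    duplicate (library-level) sample registrations inflating the archive."""
    n_pass, n_total = counts["sample_count_match"]
    return _spec([
        (ViolationProfile.of(), n_pass),
        (ViolationProfile.of("duplicate_sample_suffix"), n_total - n_pass),
    ], seed, reads)


def read_group_cohort(counts: Counts, seed: int, reads: int = 5000) -> CohortSpec:
    """Alignment-archiving studies, a subset with read groups stripped."""
    n_pass, n_total = counts["bam_has_rg"]
    return _spec([
        (ViolationProfile.of(), n_pass),
        (ViolationProfile.of("no_read_groups"), n_total - n_pass),
    ], seed, reads)


def sm_matching_cohort(counts: Counts, seed: int, reads: int = 5000) -> CohortSpec:
    """SM-bearing studies, a subset whose SM values match nothing in the
    archive metadata."""
    n_pass, n_total = counts["bam_sm_matches"]
    return _spec([
        (ViolationProfile.of(), n_pass),
        (ViolationProfile.of("sm_mismatch"), n_total - n_pass),
    ], seed, reads)


def geography_cohort(counts: Counts, seed: int, reads: int = 5000) -> CohortSpec:
    """One cohort realising the geography marginals jointly: studies with
    coordinates, with a dedicated field only, with free-text geography
    only, and with none at all."""
    n_geo, n_total = counts["geo_any"]
    n_dedicated, _ = counts["geo_dedicated"]
    n_coords, _ = counts["geo_coords"]
    freetext = n_geo - n_dedicated
    dedicated_no_coords = n_dedicated - n_coords
    assert min(n_coords, dedicated_no_coords, freetext) >= 0
    return _spec([
        (ViolationProfile.of(), n_coords),
        (ViolationProfile.of("no_coords"), dedicated_no_coords),
        (ViolationProfile.of("geo_freetext_only"), freetext),
        (ViolationProfile.of("no_geo"), n_total - n_geo),
    ], seed, reads)


def archival_completeness_cohort(counts: Counts, seed: int, reads: int = 5000) -> CohortSpec:
    """Studies declaring a studied-sample total, a subset archiving data for
    fewer samples than studied."""
    n_pass, n_total = counts["all_samples_archived"]
    return _spec([
        (ViolationProfile.of(), n_pass),
        (ViolationProfile.of("under_archive(1)"), n_total - n_pass),
    ], seed, reads)


def generate_and_audit(
    spec: CohortSpec,
    out_dir: Union[str, Path],
    config: Optional[AuditConfig] = None,
) -> CohortSummary:
    """Generate a cohort, audit every study end to end from its files and
    metadata, and aggregate the verdicts."""
    cfg = config or AuditConfig()
    bundles, _ = generate_cohort(spec, out_dir)
    verdicts = []
    for bundle in bundles:
        study_dir = Path(out_dir) / bundle.study.accession
        verdicts.append(audit_study(bundle, data_dir=study_dir, config=cfg).verdict)
    return aggregate(verdicts)
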