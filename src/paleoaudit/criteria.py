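"""The audit rubric: per-study evaluation of every survey criterion.

Each criterion carries an explicit applicability rule — mirroring the
varying denominators of the survey tables (adapter trimming is only
assessable for studies that archived raw reads, read-group criteria only
for studies that archived alignments, and so on).  A criterion whose inputs
are unavailable is *indeterminate*, not failed, and is excluded from cohort
denominators.

The registry covers five thematic tables (raw-read archiving, alignment
archiving, experiment metadata, sample metadata, negative-experiment
reporting) plus a step-by-step submission lint over the best-practice
protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .archive_model import AnalysisRecord, FileRef, RunRecord, StudyBundle
from .config import AuditConfig
from .crosscheck import (
    compare_sample_counts,
    count_distinct_sm,
    detect_duplicate_samples,
    match_rg_library,
    match_rg_sample,
)
from .metadata_audit import audit_experiment_metadata, audit_sample_metadata
from .seqcheck import (
    SeqFileStats,
    classify_file_role,
    infer_hard_filters,
    validate_alignment_file,
)

__all__ = [
    "CriterionDef",
    "CriterionVerdict",
    "StudyVerdict",
    "EvaluationError",
    "CRITERIA",
    "list_criteria",
    "evaluate_study",
    "lint_submission",
    "LINT_STEPS",
]


class EvaluationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CriterionDef:
    criterion_id: str
    table_ref: str
    label: str
    applicability: str
    pass_rule: str


@dataclass
class CriterionVerdict:
    criterion_id: str
    applicable: bool
    passed: Optional[bool] = None  # None = not applicable or indeterminate
    evidence: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.passed is not None:
            assert self.applicable
        if self.passed is False:
            assert self.evidence, "failing verdicts must carry evidence"


@dataclass
class StudyVerdict:
    study_accession: str
    verdicts: dict[str, CriterionVerdict]
    config_fingerprint: str

    def failing(self) -> list[str]:
        return [cid for cid, v in self.verdicts.items() if v.passed is False]


#: registry in table order; labels follow the survey table row wording
CRITERIA: tuple[CriterionDef, ...] = (
    # --- raw reads
    CriterionDef("raw_reads_archived", "Table 1", "Archived raw reads",
                 "all studies", "some file holds raw (unaligned or unmapped-retaining) reads"),
    CriterionDef("capture_raw", "Table 1", "Used capture technology, and archived raw reads",
                 "studies declaring capture use", "raw reads archived"),
    CriterionDef("adapters_trimmed", "Table 1", "Trimmed adapter sequences",
                 "studies archiving raw reads", "adapter residue fraction at or below threshold in every raw file"),
    # --- read alignments
    CriterionDef("alignments_archived", "Table 2", "Archived read alignments",
                 "all studies", "some file holds read alignments"),
    CriterionDef("both_archived", "Table 2", "Archived both raw reads and read alignments",
                 "all studies", "raw reads and alignments both archived"),
    CriterionDef("alignments_as_analysis", "Table 2",
                 "Archived read alignments, and did so as analysis files",
                 "studies archiving alignments", "every alignment file registered as an analysis record, none as a run"),
    CriterionDef("no_any_hardfilter", "Table 2",
                 "Archived read alignments, and did so without any apparent hard filtering of reads",
                 "studies archiving alignments", "neither MAPQ nor length hard-filter signature"),
    CriterionDef("no_mapq_hardfilter", "Table 2",
                 "Archived read alignments, and did so without hard filtering on mapping quality",
                 "studies archiving alignments", "no MAPQ hard-filter signature"),
    CriterionDef("no_length_hardfilter", "Table 2",
                 "Archived read alignments, and did so without hard filtering on read length",
                 "studies archiving alignments", "no read-length hard-filter signature"),
    CriterionDef("rawless_unfiltered", "Table 2",
                 "Did not archive raw reads. Archived read alignments, and did so without any apparent hard filtering of reads",
                 "studies archiving alignments but not raw reads", "no hard-filter signature"),
    # --- experiment metadata
    CriterionDef("sample_count_match", "Table 3",
                 "Sample number in archive matches sample number described in the paper",
                 "studies with a declared analysed-sample count", "distinct samples with data equals declared count"),
    CriterionDef("libraries_linked_single_sample", "Table 3",
                 "Libraries from the same sample are correctly linked to a single sample accession",
                 "all studies", "no informal duplicate sample registrations (alias suffix pattern)"),
    CriterionDef("accession_reuse", "Table 3",
                 "Archived new data from previously published samples, and correctly reused existing sample accessions",
                 "studies declaring previously published samples", "every declared existing accession present in the bundle"),
    CriterionDef("library_metadata_present", "Table 3",
                 "Included technical library preparation details in archive metadata",
                 "studies with registered runs", "library construction protocol or protocol keywords on some run"),
    CriterionDef("bam_has_rg", "Table 3", "BAM files have read groups",
                 "studies archiving alignments", "some alignment file declares read groups"),
    CriterionDef("bam_sm_present", "Table 3", "BAM files have SM (sample) read group fields",
                 "alignment-archiving studies with read groups", "some read group carries an SM tag"),
    CriterionDef("bam_sm_matches", "Table 3",
                 "BAM files have SM read group fields, and the sample name here matches the sample name in the archive metadata",
                 "studies with SM tags", "every SM value matches the linked sample's alias, accession or title"),
    CriterionDef("bam_single_sm", "Table 3",
                 "BAM files corresponding to a single sample contain only a single sample name in SM read group fields",
                 "studies with SM tags", "at most one distinct SM value per alignment file"),
    CriterionDef("bam_lb_present", "Table 3", "BAM files have LB (library) read group fields",
                 "studies archiving alignments", "some read group carries an LB tag"),
    CriterionDef("bam_lb_matches", "Table 3",
                 "BAM files have LB read group fields, and the library name matches the library name in the archive metadata",
                 "studies with LB tags", "every LB value matches a linked library name"),
    CriterionDef("bam_valid", "Table 3", "BAM file passes validation",
                 "studies archiving alignments", "no validation issues (rules V1-V7) in any alignment file"),
    # --- sample metadata
    CriterionDef("geo_any", "Table 4", "Metadata contains any geographical information",
                 "all studies", "geographical information found for some sample"),
    CriterionDef("geo_dedicated", "Table 4",
                 "Metadata contains geographical information, and represents this in a dedicated metadata field",
                 "studies with geographical information", "dedicated geography field on some sample"),
    CriterionDef("geo_coords", "Table 4",
                 "Metadata contains geographical information, and includes geographical coordinates",
                 "studies with geographical information", "parseable latitude/longitude on some sample"),
    CriterionDef("date_any", "Table 4", "Metadata contains any information on dating of the sample",
                 "all studies", "dating information found for some sample"),
    CriterionDef("date_dedicated", "Table 4",
                 "Metadata contains dating information, and represents this in a dedicated metadata field",
                 "studies with dating information", "dedicated date field on some sample"),
    CriterionDef("date_c14", "Table 4",
                 "Metadata contains dating information, and includes radiocarbon lab codes",
                 "studies with dating information", "radiocarbon lab code on some sample"),
    CriterionDef("tissue_any", "Table 4", "Metadata contains any information on sampled tissue",
                 "all studies", "tissue information found for some sample"),
    CriterionDef("tissue_dedicated", "Table 4",
                 "Metadata contains tissue information, and represents this in a dedicated metadata field",
                 "studies with tissue information", "dedicated tissue field on some sample"),
    CriterionDef("voucher_present", "Table 4",
                 "Metadata contains any reference to the museum/collection/excavation origin or identity of the sample",
                 "all studies", "voucher/biological-material field on some sample"),
    # --- negative-experiment reporting
    CriterionDef("total_reported", "Table 5",
                 "Paper mentions the total number of studied samples, even if some were left out from analyses",
                 "studies with a paper report", "declared total-reported flag set"),
    CriterionDef("all_samples_archived", "Table 5",
                 "Data from all studied samples appears to have been archived, even if some were left out from analyses",
                 "studies declaring a studied-sample total", "distinct samples with data >= declared studied total"),
)

_REGISTRY = {c.criterion_id: c for c in CRITERIA}
assert len(_REGISTRY) == len(CRITERIA)


def list_criteria() -> tuple[CriterionDef, ...]:
    """Registry of all criteria, in stable table order."""
    return CRITERIA


# ---------------------------------------------------------------------------


def _normalise_stats(
    file_stats: Optional[Mapping], bundle: StudyBundle
) -> Optional[dict[str, SeqFileStats]]:
    if file_stats is None:
        return None
    out: dict[str, SeqFileStats] = {}
    for key, st in file_stats.items():
        out[key.path if isinstance(key, FileRef) else str(key)] = st
    for fr in bundle.all_files():
        if fr.path not in out:
            raise EvaluationError(
                f"no statistics supplied for referenced file {fr.path!r}"
            )
    return out


def evaluate_study(
    bundle: StudyBundle,
    file_stats: Optional[Mapping] = None,
    config: Optional[AuditConfig] = None,
    validation_issues: Optional[Mapping[str, list]] = None,
    data_dir: Optional[Union[str, Path]] = None,
) -> StudyVerdict:
    """Evaluate every registry criterion for one study.

    ``file_stats`` maps file path (or :class:`FileRef`) to
    :class:`SeqFileStats` for every file referenced by the bundle; pass
    None to disable file checks, which leaves file-dependent criteria
    indeterminate.  ``validation_issues`` may pre-supply
    :func:`validate_alignment_file` results keyed by path; otherwise
    validation runs on files found on disk.

    Deterministic given bundle + stats + config, including evidence order.
    """
    cfg = config or AuditConfig()
    bundle.validate()
    stats = _normalise_stats(file_stats, bundle)
    checks_on = stats is not None

    verdicts: dict[str, CriterionVerdict] = {}

    def emit(cid, applicable, passed=None, evidence=()):
        verdicts[cid] = CriterionVerdict(cid, applicable, passed, list(evidence))

    def indeterminate(cid, why):
        verdicts[cid] = CriterionVerdict(cid, True, None, [why])

    # ---- file roles
    run_files: list[tuple[RunRecord, FileRef]] = [
        (r, f) for r in bundle.runs for f in r.files
    ]
    analysis_files: list[tuple[AnalysisRecord, FileRef]] = [
        (a, f) for a in bundle.analyses for f in a.files
    ]
    all_refs = [f for _, f in run_files] + [f for _, f in analysis_files]

    roles: dict[str, str] = {}
    if checks_on:
        for fr in all_refs:
            roles[fr.path] = classify_file_role(stats[fr.path], fr.declared_format)
    raw_paths = [p for p, role in roles.items() if role in ("raw_reads", "aligned_with_unmapped")]
    aln_paths = [p for p, role in roles.items() if role in ("aligned_only", "aligned_with_unmapped")]
    raw_present = bool(raw_paths)
    aln_present = bool(aln_paths)

    # ---- Table 1
    if not checks_on:
        indeterminate("raw_reads_archived", "file checks disabled")
    else:
        emit(
            "raw_reads_archived", True, raw_present,
            [f"{p}: {roles[p]}" for p in sorted(roles)] or ["no data files"],
        )
    capture = bool(bundle.paper_report and bundle.paper_report.used_capture)
    if not capture:
        emit("capture_raw", False)
    elif not checks_on:
        indeterminate("capture_raw", "file checks disabled")
    else:
        emit("capture_raw", True, raw_present,
             [f"{p}: {roles[p]}" for p in sorted(roles)] or ["no data files"])

    if not checks_on:
        indeterminate("adapters_trimmed", "file checks disabled")
    elif not raw_present:
        emit("adapters_trimmed", False)
    else:
        offending = [
            p for p in sorted(raw_paths)
            if stats[p].adapter_residue_fraction > cfg.adapter_threshold
        ]
        emit(
            "adapters_trimmed", True, not offending,
            [
                f"{p}: adapter residue fraction "
                f"{stats[p].adapter_residue_fraction:.4f}"
                for p in sorted(raw_paths)
            ],
        )

    # ---- Table 2
    if not checks_on:
        for cid in ("alignments_archived", "both_archived", "alignments_as_analysis",
                    "no_any_hardfilter", "no_mapq_hardfilter", "no_length_hardfilter",
                    "rawless_unfiltered"):
            indeterminate(cid, "file checks disabled")
    else:
        emit("alignments_archived", True, aln_present,
             [f"{len(aln_paths)} alignment file(s)"])
        emit("both_archived", True, raw_present and aln_present,
             [f"raw={raw_present} alignments={aln_present}"])
        if not aln_present:
            for cid in ("alignments_as_analysis", "no_any_hardfilter",
                        "no_mapq_hardfilter", "no_length_hardfilter",
                        "rawless_unfiltered"):
                emit(cid, False)
        else:
            aln_set = set(aln_paths)
            in_runs = sorted(f.path for _, f in run_files if f.path in aln_set)
            in_analyses = {f.path for _, f in analysis_files}
            ok = not in_runs and aln_set <= in_analyses
            emit("alignments_as_analysis", True, ok,
                 [f"alignment files registered as runs: {in_runs or 'none'}"])

            sigs = {p: infer_hard_filters(
                stats[p], cfg.mapq_trigger, cfg.length_trigger, cfg.min_confident_n
            ) for p in sorted(aln_set)}
            mapq_flags = [s.mapq_filtered for s in sigs.values()]
            len_flags = [s.length_filtered for s in sigs.values()]
            all_confident = all(s.confident for s in sigs.values())

            def filter_verdict(cid, flags, detail):
                if any(flags):
                    emit(cid, True, False, detail)
                elif all_confident:
                    emit(cid, True, True, detail)
                else:
                    indeterminate(cid, "insufficient reads for confident inference")

            mapq_detail = [
                f"{p}: min MAPQ {stats[p].min_mapq_mapped}" for p in sigs
            ]
            len_detail = [f"{p}: min length {stats[p].min_length}" for p in sigs]
            filter_verdict("no_mapq_hardfilter", mapq_flags, mapq_detail)
            filter_verdict("no_length_hardfilter", len_flags, len_detail)
            filter_verdict("no_any_hardfilter",
                           [m or l for m, l in zip(mapq_flags, len_flags)],
                           mapq_detail + len_detail)
            if raw_present:
                emit("rawless_unfiltered", False)
            else:
                v = verdicts["no_any_hardfilter"]
                emit("rawless_unfiltered", True, v.passed, list(v.evidence))

    # ---- Table 3
    cc = compare_sample_counts(bundle)
    if cc.declared is None:
        emit("sample_count_match", False)
    else:
        emit("sample_count_match", True, cc.matched,
             [f"declared {cc.declared}, observed {cc.observed}"])

    suffix_groups = [
        g for g in detect_duplicate_samples(
            bundle.samples, None, cfg.suffix_tokens)
        if g.reason == "suffix_pattern"
    ]
    emit("libraries_linked_single_sample", True, not suffix_groups,
         [f"duplicate alias group: {', '.join(g.member_accessions)}"
          for g in suffix_groups] or ["no duplicate alias groups"])

    declared_prev = (
        bundle.paper_report.previously_published_samples
        if bundle.paper_report else []
    )
    if not declared_prev:
        emit("accession_reuse", False)
    else:
        reuse_failures = [
            g for g in detect_duplicate_samples(
                bundle.samples, bundle.paper_report, cfg.suffix_tokens)
            if g.reason == "declared"
        ]
        emit("accession_reuse", True, not reuse_failures,
             [f"existing accession not reused: {', '.join(g.member_accessions)}"
              for g in reuse_failures]
             or [f"{len(declared_prev)} previously published sample(s) correctly reused"])

    if not bundle.runs:
        emit("library_metadata_present", False)
    else:
        hits = []
        for r in bundle.runs:
            finding = audit_experiment_metadata(r, cfg.lexicons)
            if finding.library_protocol_present:
                hits.append(
                    f"{r.accession}: {sorted(finding.protocol_keywords) or 'protocol text'}"
                )
        emit("library_metadata_present", True, bool(hits),
             hits or ["no run carries library preparation details"])

    # read-group criteria
    if not checks_on:
        for cid in ("bam_has_rg", "bam_sm_present", "bam_sm_matches",
                    "bam_single_sm", "bam_lb_present", "bam_lb_matches",
                    "bam_valid"):
            indeterminate(cid, "file checks disabled")
    elif not aln_present:
        for cid in ("bam_has_rg", "bam_sm_present", "bam_sm_matches",
                    "bam_single_sm", "bam_lb_present", "bam_lb_matches",
                    "bam_valid"):
            emit(cid, False)
    else:
        aln_sorted = sorted(set(aln_paths))
        rg_lists = {p: stats[p].read_groups for p in aln_sorted}
        any_rg = any(rg_lists[p] for p in aln_sorted)
        emit("bam_has_rg", True, any_rg,
             [f"{p}: {len(rg_lists[p])} read group(s)" for p in aln_sorted])
        if not any_rg:
            emit("bam_sm_present", False)
            emit("bam_sm_matches", False)
            emit("bam_single_sm", False)
        else:
            sm_by_file = {p: stats[p].distinct_sm_values for p in aln_sorted}
            any_sm = any(sm_by_file.values())
            emit("bam_sm_present", True, any_sm,
                 [f"{p}: SM values {sorted(sm_by_file[p]) or 'absent'}"
                  for p in aln_sorted])
            if not any_sm:
                emit("bam_sm_matches", False)
                emit("bam_single_sm", False)
            else:
                file_sample = _file_sample_map(bundle)
                mismatches = []
                for p in aln_sorted:
                    if not sm_by_file[p]:
                        continue
                    s_acc = file_sample.get(p)
                    if s_acc is None:
                        mismatches.append(f"{p}: no linked sample")
                        continue
                    sample = bundle.sample_by_accession(s_acc)
                    res = match_rg_sample(
                        rg_lists[p], sample, cfg.case_insensitive_match)
                    if not res.matched:
                        mismatches.append(
                            f"{p}: SM {res.left_value!r} does not match "
                            f"{list(res.candidate_values)}"
                        )
                emit("bam_sm_matches", True, not mismatches,
                     mismatches or ["all SM values match archive metadata"])
                multi = [p for p in aln_sorted if count_distinct_sm(stats[p]) > 1]
                emit("bam_single_sm", True, not multi,
                     [f"{p}: {sorted(sm_by_file[p])}" for p in multi]
                     or ["single SM value per file"])
        any_lb = any(
            rg.library_tag for p in aln_sorted for rg in rg_lists[p]
        )
        emit("bam_lb_present", True, any_lb,
             [f"{p}: LB values "
              f"{sorted({rg.library_tag for rg in rg_lists[p] if rg.library_tag}) or 'absent'}"
              for p in aln_sorted])
        if not any_lb:
            emit("bam_lb_matches", False)
        else:
            file_sample = _file_sample_map(bundle)
            lb_mismatches = []
            for p in aln_sorted:
                if not any(rg.library_tag for rg in rg_lists[p]):
                    continue
                s_acc = file_sample.get(p)
                runs = bundle.runs_for_sample(s_acc) if s_acc else []
                res = match_rg_library(rg_lists[p], runs, cfg.case_insensitive_match)
                if not res.matched:
                    lb_mismatches.append(
                        f"{p}: LB {res.left_value!r} does not match "
                        f"{list(res.candidate_values)}"
                    )
            emit("bam_lb_matches", True, not lb_mismatches,
                 lb_mismatches or ["all LB values match archive metadata"])

        issue_map = {}
        missing = []
        for p in aln_sorted:
            resolved = Path(p)
            if not resolved.is_absolute() and data_dir is not None:
                resolved = Path(data_dir) / p
            if validation_issues is not None and p in validation_issues:
                issue_map[p] = list(validation_issues[p])
            elif resolved.exists():
                issue_map[p] = validate_alignment_file(
                    FileRef(str(resolved), stats[p].declared_format), cfg.n_sample)
            else:
                missing.append(p)
        if missing:
            indeterminate("bam_valid",
                          f"files not available for validation: {missing}")
        else:
            flat = [
                f"{p}: {i.rule_id} {i.detail}"
                for p in aln_sorted for i in issue_map[p]
            ]
            emit("bam_valid", True, not flat,
                 flat or ["no validation issues"])

    # ---- Table 4
    findings = [
        (s.accession, audit_sample_metadata(s, cfg.lexicons))
        for s in bundle.samples
    ]

    def sample_level(cid, any_pred, parent=None, detail=lambda acc, f: acc):
        if not findings:
            indeterminate(cid, "no samples registered")
            return
        if parent is not None and verdicts[parent].passed is not True:
            emit(cid, False)
            return
        hits = [detail(acc, f) for acc, f in findings if any_pred(f)]
        emit(cid, True, bool(hits), hits or ["no sample provides this information"])

    sample_level("geo_any", lambda f: f.geo_any,
                 detail=lambda acc, f: f"{acc}: "
                 + "; ".join(str(e) for e in f.evidence if e[0].startswith("geo")))
    sample_level("geo_dedicated", lambda f: f.geo_dedicated_field, parent="geo_any")
    sample_level("geo_coords", lambda f: f.geo_coordinates, parent="geo_any",
                 detail=lambda acc, f: f"{acc}: ({f.parsed_lat}, {f.parsed_lon})")
    sample_level("date_any", lambda f: f.date_any)
    sample_level("date_dedicated", lambda f: f.date_dedicated_field, parent="date_any")
    sample_level("date_c14", lambda f: f.c14_lab_code is not None, parent="date_any",
                 detail=lambda acc, f: f"{acc}: {f.c14_lab_code}")
    sample_level("tissue_any", lambda f: f.tissue_any)
    sample_level("tissue_dedicated", lambda f: f.tissue_dedicated_field,
                 parent="tissue_any")
    sample_level("voucher_present", lambda f: f.voucher_present)

    # ---- Table 5
    pr = bundle.paper_report
    if pr is None:
        emit("total_reported", False)
        emit("all_samples_archived", False)
    else:
        emit("total_reported", True, pr.total_reported_in_paper,
             [f"total_reported_in_paper={pr.total_reported_in_paper}"])
        if pr.n_samples_studied_total is None:
            emit("all_samples_archived", False)
        else:
            emit("all_samples_archived", True,
                 cc.observed >= pr.n_samples_studied_total,
                 [f"studied total {pr.n_samples_studied_total}, "
                  f"archived with data {cc.observed}"])

    # completeness + registry order
    ordered = {c.criterion_id: verdicts[c.criterion_id] for c in CRITERIA}
    assert len(ordered) == len(CRITERIA)
    return StudyVerdict(bundle.study.accession, ordered, cfg.fingerprint())


def _file_sample_map(bundle: StudyBundle) -> dict[str, str]:
    """Map each data-file path to its (single) linked sample accession."""
    out: dict[str, str] = {}
    for r in bundle.runs:
        for f in r.files:
            out[f.path] = r.sample_accession
    run_sample = {r.accession: r.sample_accession for r in bundle.runs}
    for a in bundle.analyses:
        s_accs = list(a.linked_sample_accessions) or [
            run_sample[r] for r in a.linked_run_accessions if r in run_sample
        ]
        for f in a.files:
            if s_accs:
                out[f.path] = s_accs[0]
    return out


# ---------------------------------------------------------------------------
# submission lint (step-by-step protocol)

#: protocol steps -> contributing criteria
LINT_STEPS: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("step1", "Register samples (reuse existing accessions; archive negatives)",
     ("sample_count_match", "libraries_linked_single_sample",
      "accession_reuse", "all_samples_archived")),
    ("step2", "Provide informative sample metadata",
     ("geo_any", "geo_dedicated", "geo_coords", "date_any", "date_dedicated",
      "date_c14", "tissue_any", "tissue_dedicated", "voucher_present")),
    ("step3", "Prepare raw reads (demultiplexed, adapter-trimmed, unfiltered)",
     ("adapters_trimmed",)),
    ("step4", "Deposit raw reads, one file per sample/library/run",
     ("raw_reads_archived", "capture_raw")),
    ("step5", "Provide experimental metadata on libraries",
     ("library_metadata_present",)),
    ("step6", "Prepare read alignments (no hard filters, correct read groups, validated)",
     ("no_any_hardfilter", "no_mapq_hardfilter", "no_length_hardfilter",
      "rawless_unfiltered", "bam_has_rg", "bam_sm_present", "bam_sm_matches",
      "bam_single_sm", "bam_lb_present", "bam_lb_matches", "bam_valid")),
    ("step7", "Deposit read alignments as analysis files",
     ("alignments_as_analysis", "both_archived")),
    ("step8", "Document archiving choices in the paper",
     ("total_reported",)),
)


def lint_submission(
    bundle: StudyBundle,
    file_stats: Optional[Mapping] = None,
    config: Optional[AuditConfig] = None,
    data_dir: Optional[Union[str, Path]] = None,
) -> dict[str, dict]:
    """Preflight checklist over the eight-step archiving protocol.

    Each step is ``ok`` when every applicable, determinate contributing
    criterion passes, ``action_needed`` when any fails, and ``not_checked``
    when none could be assessed (e.g. no paper report for the
    documentation step).
    """
    verdict = evaluate_study(bundle, file_stats, config, data_dir=data_dir)
    report: dict[str, dict] = {}
    for step_id, title, cids in LINT_STEPS:
        assessed = {
            cid: verdict.verdicts[cid]
            for cid in cids
            if verdict.verdicts[cid].passed is not None
        }
        if not assessed:
            status = "not_checked"
        elif any(v.passed is False for v in assessed.values()):
            status = "action_needed"
        else:
            status = "ok"
        report[step_id] = {
            "title": title,
            "status": status,
            "criteria": {
                cid: (None if v.passed is None else bool(v.passed))
                for cid, v in (
                    (cid, verdict.verdicts[cid]) for cid in cids
                )
            },
        }
    return report
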