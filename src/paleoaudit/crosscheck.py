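"""Cross-record consistency checks.

Links what is inside the data files (read-group SM/LB tags) to the archive
metadata (sample aliases, library names), and the archive metadata to
author-declared facts (sample counts, previously published samples).
Matching is exact after whitespace trimming by default — automated reuse of
archived data depends on identifiers matching by machine, not by eye — with
an optional case-insensitive mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .archive_model import PaperReport, RunRecord, SampleRecord, StudyBundle
from .seqcheck import ReadGroupInfo, SeqFileStats

__all__ = [
    "MatchResult",
    "CountComparison",
    "DuplicateGroup",
    "DEFAULT_SUFFIX_TOKENS",
    "match_rg_sample",
    "match_rg_library",
    "count_distinct_sm",
    "detect_duplicate_samples",
    "compare_sample_counts",
]

#: alias suffix tokens that suggest an informal duplicate registration
DEFAULT_SUFFIX_TOKENS = ("new", "ss", "capture", "repeat", "rerun", "v2")


@dataclass(frozen=True)
class MatchResult:
    matched: bool
    left_value: str
    candidate_values: tuple[str, ...]
    match_kind: str  # exact | normalized | none

    def __post_init__(self):
        assert self.matched == (self.match_kind != "none")


@dataclass(frozen=True)
class CountComparison:
    declared: Optional[int]
    observed: int
    matched: bool

    def __post_init__(self):
        assert self.matched == (self.declared is not None and self.declared == self.observed)


@dataclass(frozen=True)
class DuplicateGroup:
    member_accessions: tuple[str, ...]
    reason: str  # suffix_pattern | declared

    def __post_init__(self):
        assert len(self.member_accessions) >= 2
        assert len(set(self.member_accessions)) == len(self.member_accessions)


def _match_values(
    values: Sequence[str], candidates: Sequence[str], case_insensitive: bool
) -> MatchResult:
    values = [v.strip() for v in values]
    cands = tuple(c.strip() for c in candidates if c and c.strip())
    if not values:
        return MatchResult(False, "", cands, "none")
    if all(v in cands for v in values):
        return MatchResult(True, values[0], cands, "exact")
    if case_insensitive:
        folded = {c.casefold() for c in cands}
        if all(v.casefold() in folded for v in values):
            return MatchResult(True, values[0], cands, "normalized")
    return MatchResult(False, values[0], cands, "none")


def match_rg_sample(
    read_groups: Iterable[ReadGroupInfo],
    sample: SampleRecord,
    case_insensitive: bool = False,
) -> MatchResult:
    """Do all SM read-group values identify the archived sample?

    Candidates are the sample's alias, accession and title.  Absent SM tags
    yield an unmatched result with kind ``none`` (flagged upstream as a
    separate criterion).
    """
    sm_values = sorted({rg.sample_tag for rg in read_groups if rg.sample_tag})
    candidates = (sample.alias, sample.accession, sample.title)
    return _match_values(sm_values, candidates, case_insensitive)


def match_rg_library(
    read_groups: Iterable[ReadGroupInfo],
    runs: Iterable[RunRecord],
    case_insensitive: bool = False,
) -> MatchResult:
    """Do all LB read-group values match archived library names of the
    sample's runs?"""
    lb_values = sorted({rg.library_tag for rg in read_groups if rg.library_tag})
    candidates = tuple(r.library_name for r in runs)
    return _match_values(lb_values, candidates, case_insensitive)


def count_distinct_sm(stats: SeqFileStats) -> int:
    """Number of distinct SM values declared in one file's read groups."""
    return len(stats.distinct_sm_values)


def _normalize_alias(alias: str, suffix_tokens: Sequence[str]) -> str:
    """Casefold, unify separators, and strip trailing duplicate-marker tokens.

    Bare trailing digits are deliberately not stripped (too many false
    merges between genuinely distinct samples like S1/S2).
    """
    norm = alias.casefold()
    for sep in ("-", ".", " "):
        norm = norm.replace(sep, "_")
    tokens = [t for t in norm.split("_") if t]
    suffixes = {t.casefold() for t in suffix_tokens}
    while len(tokens) > 1 and tokens[-1] in suffixes:
        tokens.pop()
    return "_".join(tokens)


def detect_duplicate_samples(
    samples: Sequence[SampleRecord],
    paper_report: Optional[PaperReport] = None,
    suffix_tokens: Sequence[str] = DEFAULT_SUFFIX_TOKENS,
) -> list[DuplicateGroup]:
    """Find informally duplicated sample registrations.

    Groups samples whose aliases coincide after normalisation (suffix-token
    stripping), and reports declared previously-published samples whose
    existing accession was *not* reused in this bundle (reuse failure).
    Groups are disjoint.
    """
    groups: list[DuplicateGroup] = []
    by_norm: dict[str, list[str]] = {}
    for s in samples:
        key = _normalize_alias(s.alias or s.accession, suffix_tokens)
        by_norm.setdefault(key, []).append(s.accession)
    for key in sorted(by_norm):
        members = by_norm[key]
        if len(members) >= 2:
            groups.append(DuplicateGroup(tuple(sorted(members)), "suffix_pattern"))

    if paper_report is not None:
        present = {s.accession for s in samples}
        alias_to_acc = {s.alias: s.accession for s in samples if s.alias}
        for alias, existing_acc in paper_report.previously_published_samples:
            if existing_acc in present:
                continue  # correctly reused
            local = alias_to_acc.get(alias, alias)
            members = tuple(sorted({local, existing_acc}))
            if len(members) >= 2:
                groups.append(DuplicateGroup(members, "declared"))
    return groups


def compare_sample_counts(bundle: StudyBundle) -> CountComparison:
    """Archived distinct samples with data vs the paper-declared count.

    Observed is the number of distinct sample accessions carrying at least
    one run or analysis file; declared is the paper's analysed-sample count.
    """
    with_data: set[str] = set()
    for r in bundle.runs:
        if r.files:
            with_data.add(r.sample_accession)
    run_sample = {r.accession: r.sample_accession for r in bundle.runs}
    for a in bundle.analyses:
        if not a.files:
            continue
        with_data.update(a.linked_sample_accessions)
        for racc in a.linked_run_accessions:
            if racc in run_sample:
                with_data.add(run_sample[racc])
    declared = (
        bundle.paper_report.n_samples_analysed if bundle.paper_report else None
    )
    observed = len(with_data)
    return CountComparison(
        declared=declared,
        observed=observed,
        matched=declared is not None and declared == observed,
    )
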