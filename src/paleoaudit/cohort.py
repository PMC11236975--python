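"""Aggregation of study verdicts into survey-style tables.

For each criterion, the cohort summary counts the studies for which it was
applicable and determinate, how many passed, and the passing percentage —
the machine twin of the survey tables.  Percentages are rounded half-up to
one decimal, with a trailing ``.0`` dropped when printed (45.0 renders as
"45%", 47.6 as "47.6%").
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .criteria import CRITERIA, StudyVerdict

__all__ = [
    "CriterionCounts",
    "CohortSummary",
    "aggregate",
    "render_table",
    "parse_rendered_tsv",
    "round_pct",
    "format_pct",
]


def round_pct(n_pass: int, n_applicable: int) -> Optional[float]:
    """Passing percentage, rounded half-up to one decimal; None when the
    denominator is zero."""
    if n_applicable == 0:
        return None
    pct = Decimal(100 * n_pass) / Decimal(n_applicable)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def format_pct(pct: Optional[float]) -> str:
    if pct is None:
        return "-"
    if float(pct) == int(pct):
        return f"{int(pct)}%"
    return f"{pct:.1f}%"


@dataclass(frozen=True)
class CriterionCounts:
    n_applicable: int
    n_pass: int
    n_fail: int
    pct_pass: Optional[float]

    def __post_init__(self):
        assert self.n_pass + self.n_fail == self.n_applicable
        if self.pct_pass is not None:
            assert 0.0 <= self.pct_pass <= 100.0


@dataclass
class CohortSummary:
    counts: dict[str, CriterionCounts]
    n_studies: int
    config_fingerprint: str

    def pct(self, criterion_id: str) -> Optional[float]:
        return self.counts[criterion_id].pct_pass


class FingerprintMismatch(ValueError):
    """Verdicts produced under different configurations are incomparable."""


def aggregate(verdicts: Sequence[StudyVerdict]) -> CohortSummary:
    """Per-criterion pass/fail counts over a cohort of study verdicts.

    Indeterminate and inapplicable verdicts are excluded from all counts.
    All verdicts must share one configuration fingerprint.
    """
    fingerprints = {v.config_fingerprint for v in verdicts}
    if len(fingerprints) > 1:
        raise FingerprintMismatch(
            f"verdicts carry {len(fingerprints)} distinct config fingerprints"
        )
    counts: dict[str, CriterionCounts] = {}
    for cdef in CRITERIA:
        cid = cdef.criterion_id
        n_pass = n_fail = 0
        for sv in verdicts:
            v = sv.verdicts[cid]
            if not v.applicable or v.passed is None:
                continue
            if v.passed:
                n_pass += 1
            else:
                n_fail += 1
        n_app = n_pass + n_fail
        counts[cid] = CriterionCounts(n_app, n_pass, n_fail, round_pct(n_pass, n_app))
    return CohortSummary(
        counts=counts,
        n_studies=len(verdicts),
        config_fingerprint=next(iter(fingerprints)) if fingerprints else "",
    )


_TABLES = ("Table 1", "Table 2", "Table 3", "Table 4", "Table 5")


def render_table(
    summary: CohortSummary,
    table_selector: Optional[str] = None,
    fmt: str = "tsv",
) -> str:
    """Render the summary as TSV or aligned text, rows in registry order.

    ``table_selector`` restricts output to one thematic table ("Table 1" ..
    "Table 5"); None renders all rows.
    """
    rows = []
    for cdef in CRITERIA:
        if table_selector is not None and cdef.table_ref != table_selector:
            continue
        c = summary.counts.get(cdef.criterion_id)
        if c is None:
            continue
        rows.append((
            cdef.criterion_id,
            cdef.label,
            c.n_pass,
            c.n_fail,
            c.n_applicable,
            c.pct_pass,
        ))
    header = ("criterion_id", "label", "n_pass", "n_fail", "n_applicable", "pct_pass")
    if fmt == "tsv":
        lines = ["\t".join(header)]
        for cid, label, n_pass, n_fail, n_app, pct in rows:
            lines.append("\t".join([
                cid, label, str(n_pass), str(n_fail), str(n_app),
                "" if pct is None else f"{pct:.1f}",
            ]))
        return "\n".join(lines) + "\n"
    if fmt == "text":
        lines = []
        for cid, label, n_pass, n_fail, n_app, pct in rows:
            meeting = f"{n_pass} ({format_pct(round_pct(n_pass, n_app))})" if n_app else "0"
            failing = f"{n_fail} ({format_pct(round_pct(n_fail, n_app))})" if n_app else "0"
            lines.append(f"{label:<110s} {meeting:>14s} {failing:>14s} {n_app:>4d}")
        head = f"{'Criterion':<110s} {'Meeting':>14s} {'Not meeting':>14s} {'N':>4s}"
        return "\n".join([head] + lines) + "\n"
    raise ValueError(f"unknown table format {fmt!r}")


def parse_rendered_tsv(text: str) -> dict[str, CriterionCounts]:
    """Re-parse a rendered TSV table back into counts (conservation check)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    out: dict[str, CriterionCounts] = {}
    for ln in lines[1:]:
        rec = dict(zip(header, ln.split("\t")))
        pct = rec["pct_pass"]
        out[rec["criterion_id"]] = CriterionCounts(
            int(rec["n_applicable"]),
            int(rec["n_pass"]),
            int(rec["n_fail"]),
            None if pct == "" else float(pct),
        )
    return out
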