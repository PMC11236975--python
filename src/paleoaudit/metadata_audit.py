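"""Completeness scoring of sample and experiment metadata.

Ancient-sample metadata lives in free-form tag/value attributes on BioSample
records.  The auditor distinguishes, per information category (geography,
dating, tissue, specimen voucher), whether the information is present *at
all* and whether it sits in a *dedicated* metadata field rather than a
general-purpose free-text one.  Detection is driven by a configurable
:class:`Lexicons` vocabulary: dedicated tag lists, a flat gazetteer of place
names, tissue terms, date patterns and radiocarbon-laboratory prefixes.

Free-text recognition here is exact lexicon matching, not named-entity
recognition; recall on arbitrary real-world text is explicitly not
guaranteed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .archive_model import RunRecord, SampleRecord

__all__ = [
    "Lexicons",
    "SampleMetadataFindings",
    "ExperimentMetadataFindings",
    "CoordinateRangeError",
    "CoordinateFormatError",
    "parse_coordinates",
    "find_c14_lab_code",
    "audit_sample_metadata",
    "audit_experiment_metadata",
]


class CoordinateFormatError(ValueError):
    pass


class CoordinateRangeError(ValueError):
    pass


@dataclass
class Lexicons:
    """Named vocabulary lists driving metadata detection (config-overridable)."""

    geo_dedicated_tags: list[str]
    date_dedicated_tags: list[str]
    tissue_dedicated_tags: list[str]
    voucher_tags: list[str]
    freetext_tags: list[str]
    tissue_terms: list[str]
    gazetteer_terms: list[str]
    date_patterns: list[str]
    c14_prefixes: list[str]
    protocol_terms: list[str]

    def __post_init__(self):
        for f in dc_fields(self):
            if not getattr(self, f.name):
                raise ValueError(f"lexicon list {f.name} must be non-empty")

    @classmethod
    def default(cls) -> "Lexicons":
        text = (
            resources.files("paleoaudit").joinpath("data/lexicons.yaml").read_text()
        )
        return cls(**yaml.safe_load(text))

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "Lexicons":
        """Load lexicons from YAML/JSON; missing lists fall back to defaults."""
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        base = cls.default()
        for f in dc_fields(cls):
            if f.name in doc:
                setattr(base, f.name, list(doc[f.name]))
        return base


@dataclass
class SampleMetadataFindings:
    geo_any: bool = False
    geo_dedicated_field: bool = False
    geo_coordinates: bool = False
    parsed_lat: Optional[float] = None
    parsed_lon: Optional[float] = None
    date_any: bool = False
    date_dedicated_field: bool = False
    c14_lab_code: Optional[str] = None
    tissue_any: bool = False
    tissue_dedicated_field: bool = False
    voucher_present: bool = False
    evidence: list[tuple[str, str, str]] = field(default_factory=list)
    # evidence entries are (finding, tag, matched_text)

    def check_invariants(self) -> None:
        assert self.geo_any or not self.geo_dedicated_field
        assert self.geo_any or not self.geo_coordinates
        assert self.date_any or not self.date_dedicated_field
        assert self.tissue_any or not self.tissue_dedicated_field
        if self.geo_coordinates:
            assert self.parsed_lat is not None and -90 <= self.parsed_lat <= 90
            assert self.parsed_lon is not None and -180 <= self.parsed_lon <= 180


@dataclass
class ExperimentMetadataFindings:
    library_protocol_present: bool = False
    protocol_keywords: set[str] = field(default_factory=set)

    def check_invariants(self) -> None:
        if self.protocol_keywords:
            assert self.library_protocol_present


# ---------------------------------------------------------------------------
# coordinate and lab-code parsing

_DEC_RE = re.compile(
    r"^\s*([+-]?\d+(?:\.\d+)?)\s*°?\s*([NSEW])?\s*$", re.IGNORECASE
)
_DMS_RE = re.compile(
    r"^\s*(\d+(?:\.\d+)?)\s*[°\s]\s*(\d+(?:\.\d+)?)\s*['\s]?\s*(\d+(?:\.\d+)?)?\s*[\"\s]?\s*([NSEW])\s*$",
    re.IGNORECASE,
)


def _parse_one_coordinate(text: str, is_lat: bool) -> float:
    m = _DEC_RE.match(text)
    if m:
        value = float(m.group(1))
        hemi = (m.group(2) or "").upper()
        if hemi in ("S", "W"):
            value = -abs(value)
        elif hemi in ("N", "E"):
            value = abs(value)
    else:
        m = _DMS_RE.match(text)
        if not m:
            raise CoordinateFormatError(f"unparseable coordinate {text!r}")
        deg = float(m.group(1))
        minutes = float(m.group(2))
        seconds = float(m.group(3) or 0.0)
        value = deg + minutes / 60.0 + seconds / 3600.0
        if m.group(4).upper() in ("S", "W"):
            value = -value
    limit = 90.0 if is_lat else 180.0
    if abs(value) > limit:
        axis = "latitude" if is_lat else "longitude"
        raise CoordinateRangeError(f"{axis} {value} outside ±{limit}")
    return value


def parse_coordinates(lat_text: str, lon_text: str) -> tuple[float, float]:
    """Parse latitude/longitude given as decimal degrees or D M S + hemisphere.

    Returns signed decimal degrees, range-checked (|lat| <= 90, |lon| <= 180).
    """
    if not lat_text or not lon_text:
        raise CoordinateFormatError("empty coordinate text")
    return (
        _parse_one_coordinate(lat_text, is_lat=True),
        _parse_one_coordinate(lon_text, is_lat=False),
    )


def find_c14_lab_code(text: str, prefixes: Optional[list[str]] = None) -> Optional[str]:
    """First radiocarbon lab code in ``text``: known prefix, optional hyphen
    or space, then 1-6 digits.  Prefix matching is case-sensitive."""
    if prefixes is None:
        prefixes = Lexicons.default().c14_prefixes
    if not prefixes:
        raise ValueError("prefixes must be non-empty")
    best: Optional[tuple[int, str]] = None
    for prefix in prefixes:
        pat = re.compile(
            r"(?<![A-Za-z])" + re.escape(prefix) + r"[- ]?(\d{1,6})(?!\d)"
        )
        m = pat.search(text)
        if m and (best is None or m.start() < best[0]):
            best = (m.start(), m.group(0))
    return best[1] if best else None


# ---------------------------------------------------------------------------
# audits

def _tag_in(tag: str, tag_list: list[str]) -> bool:
    return tag.strip().lower() in {t.strip().lower() for t in tag_list}


def _term_match(value: str, terms: list[str]) -> Optional[str]:
    """Word-boundary, case-insensitive match of any term within a value."""
    low = value.lower()
    for term in terms:
        if re.search(r"(?<!\w)" + re.escape(term.lower()) + r"(?!\w)", low):
            return term
    return None


def _pattern_match(value: str, patterns: list[str]) -> Optional[str]:
    for pat in patterns:
        m = re.search(pat, value, flags=re.IGNORECASE)
        if m:
            return m.group(0)
    return None


def audit_sample_metadata(
    sample: SampleRecord, lexicons: Optional[Lexicons] = None
) -> SampleMetadataFindings:
    """Score one sample's metadata completeness.

    Dedicated findings fire only on attributes whose tag is in the relevant
    dedicated list; "any" findings fire on dedicated hits or on lexicon /
    pattern matches in free-text fields (Description-like tags and the
    record title).  Every positive finding carries evidence naming the tag
    that fired.
    """
    lex = lexicons or Lexicons.default()
    f = SampleMetadataFindings()

    free_texts: list[tuple[str, str]] = []
    if sample.title:
        free_texts.append(("title", sample.title))
    lat_text = lon_text = latlon_text = None

    for attr in sample.attributes:
        tag, value = attr.tag, attr.value
        low = tag.strip().lower()
        if _tag_in(tag, lex.geo_dedicated_tags) and value.strip():
            f.geo_any = True
            f.geo_dedicated_field = True
            f.evidence.append(("geo_dedicated", tag, value))
            if "latitude" in low:
                lat_text = value
            elif "longitude" in low:
                lon_text = value
            elif low == "lat_lon":
                latlon_text = value
        if _tag_in(tag, lex.date_dedicated_tags) and value.strip():
            f.date_any = True
            f.date_dedicated_field = True
            f.evidence.append(("date_dedicated", tag, value))
        if _tag_in(tag, lex.tissue_dedicated_tags) and value.strip():
            f.tissue_any = True
            f.tissue_dedicated_field = True
            f.evidence.append(("tissue_dedicated", tag, value))
        if _tag_in(tag, lex.voucher_tags) and value.strip():
            f.voucher_present = True
            f.evidence.append(("voucher", tag, value))
        if _tag_in(tag, lex.freetext_tags):
            free_texts.append((tag, value))
        code = find_c14_lab_code(value, lex.c14_prefixes)
        if code and f.c14_lab_code is None:
            f.c14_lab_code = code
            f.evidence.append(("c14_lab_code", tag, code))

    for tag, text in free_texts:
        hit = _term_match(text, lex.gazetteer_terms)
        if hit and not f.geo_any:
            f.geo_any = True
            f.evidence.append(("geo_freetext", tag, hit))
        elif hit and not any(e[0].startswith("geo") for e in f.evidence):
            f.evidence.append(("geo_freetext", tag, hit))
        hit = _pattern_match(text, lex.date_patterns)
        if hit:
            if not f.date_any:
                f.evidence.append(("date_freetext", tag, hit))
            f.date_any = True
        hit = _term_match(text, lex.tissue_terms)
        if hit:
            if not f.tissue_any:
                f.evidence.append(("tissue_freetext", tag, hit))
            f.tissue_any = True

    # dating may also be evidenced solely by a radiocarbon lab code
    if f.c14_lab_code is not None:
        f.date_any = True

    if latlon_text is not None and (lat_text is None or lon_text is None):
        parts = latlon_text.split()
        if len(parts) == 4:  # "52.2 N 0.12 E"
            lat_text, lon_text = " ".join(parts[:2]), " ".join(parts[2:])
        elif len(parts) == 2:
            lat_text, lon_text = parts
    if lat_text is not None and lon_text is not None:
        try:
            f.parsed_lat, f.parsed_lon = parse_coordinates(lat_text, lon_text)
            f.geo_coordinates = True
            f.evidence.append(
                ("geo_coordinates", "latitude/longitude", f"{lat_text} / {lon_text}")
            )
        except (CoordinateFormatError, CoordinateRangeError) as exc:
            f.evidence.append(("geo_coordinates_unparseable", "latitude/longitude", str(exc)))

    f.check_invariants()
    return f


def audit_experiment_metadata(
    run: RunRecord, lexicons: Optional[Lexicons] = None
) -> ExperimentMetadataFindings:
    """Detect technical library-preparation details on one run record.

    Present when the dedicated library-construction-protocol field is
    non-empty, or when protocol terms (single-/double-stranded, UDG, USER,
    ...) appear in any run attribute.
    """
    lex = lexicons or Lexicons.default()
    f = ExperimentMetadataFindings()
    texts: list[str] = []
    if run.library_construction_protocol:
        f.library_protocol_present = True
        texts.append(run.library_construction_protocol)
    texts.extend(a.value for a in run.attributes)
    for text in texts:
        for term in lex.protocol_terms:
            if re.search(r"(?<!\w)" + re.escape(term.lower()) + r"(?!\w)", text.lower()):
                f.protocol_keywords.add(term)
                f.library_protocol_present = True
    f.check_invariants()
    return f
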