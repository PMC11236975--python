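"""Metadata completeness: coordinates, lab codes, sample/experiment audits."""

import numpy as np
import pytest

from paleoaudit.archive_model import Attribute, RunRecord, SampleRecord
from paleoaudit.metadata_audit import (
    CoordinateFormatError,
    CoordinateRangeError,
    Lexicons,
    audit_experiment_metadata,
    audit_sample_metadata,
    find_c14_lab_code,
    parse_coordinates,
)

LEX = Lexicons.default()


# ---------------------------------------------------------------------------
# coordinates


@pytest.mark.parametrize("lat,lon,expected", [
    ("0", "0", (0.0, 0.0)),
    ("52 12 0 N", "0 7 0 E", (52.2, 0.116667)),  # D + M/60 + S/3600 by hand
    ("-12.5", "130.25", (-12.5, 130.25)),
    ("33 30 S", "70 40 W", (-33.5, -(70 + 40 / 60))),
    ("52.2 N", "0.12 E", (52.2, 0.12)),
])
def test_parse_coordinates_decimal_and_sexagesimal(lat, lon, expected):
    got = parse_coordinates(lat, lon)
    assert got == pytest.approx(expected, abs=1e-6)


def test_out_of_range_coordinates_rejected():
    with pytest.raises(CoordinateRangeError):
        parse_coordinates("95", "10")
    with pytest.raises(CoordinateRangeError):
        parse_coordinates("10", "181")


def test_unparseable_coordinates_rejected():
    with pytest.raises(CoordinateFormatError):
        parse_coordinates("somewhere north", "10")
    with pytest.raises(CoordinateFormatError):
        parse_coordinates("", "10")


# ---------------------------------------------------------------------------
# radiocarbon lab codes


def brute_force_c14_scan(text, prefixes):
    """Regex-free oracle: try every substring start for prefix + optional
    separator + 1-6 digits, earliest match wins."""
    best = None
    for prefix in prefixes:
        for i in range(len(text) - len(prefix) + 1):
            if text[i:i + len(prefix)] != prefix:
                continue
            if i > 0 and text[i - 1].isalpha():
                continue
            j = i + len(prefix)
            k = j + 1 if j < len(text) and text[j] in "- " else j
            d = k
            while d < len(text) and text[d].isdigit() and d - k < 6:
                d += 1
            if d == k or (d < len(text) and text[d].isdigit()):
                continue
            if best is None or i < best[0]:
                best = (i, text[i:d])
    return best[1] if best else None


def test_lab_code_found_in_dating_text():
    assert find_c14_lab_code("4520±30 BP (OxA-12345)") == "OxA-12345"


def test_no_code_in_plain_prose():
    assert find_c14_lab_code("dated to the Bronze Age") is None


def test_lab_code_matches_brute_force_scan_on_planted_texts():
    rng = np.random.default_rng(17)
    prefixes = LEX.c14_prefixes
    fillers = ["bone sample", "radiocarbon dated", "ca. 4200 BP", "museum id 77",
               "OxAx999 not a code", "see table"]
    for _ in range(20):
        parts = list(rng.choice(fillers, size=3))
        if rng.random() < 0.7:
            pref = prefixes[int(rng.integers(len(prefixes)))]
            sep = ["-", " ", ""][int(rng.integers(3))]
            code = f"{pref}{sep}{int(rng.integers(1, 999999))}"
            parts.insert(int(rng.integers(len(parts) + 1)), code)
        text = ", ".join(parts)
        assert find_c14_lab_code(text, prefixes) == brute_force_c14_scan(text, prefixes)


# ---------------------------------------------------------------------------
# sample metadata audit


def _sample(*attrs, title=""):
    return SampleRecord("SAMT1", alias="IND1", title=title,
                        attributes=[Attribute(t, v) for t, v in attrs])


def test_empty_sample_yields_all_false():
    f = audit_sample_metadata(_sample(), LEX)
    assert not any([f.geo_any, f.date_any, f.tissue_any, f.voucher_present,
                    f.geo_dedicated_field, f.geo_coordinates])
    assert f.evidence == []


def test_dedicated_geography_field_fires_both_levels():
    f = audit_sample_metadata(
        _sample(("geographic location (region and locality)", "Norfolk, UK")), LEX)
    assert f.geo_any and f.geo_dedicated_field and not f.geo_coordinates
    assert any(e[0] == "geo_dedicated" for e in f.evidence)


def test_description_bone_is_tissue_any_but_not_dedicated():
    f = audit_sample_metadata(_sample(("Description", "Bone")), LEX)
    assert f.tissue_any and not f.tissue_dedicated_field


def test_freetext_gazetteer_and_date_pattern_hits():
    f = audit_sample_metadata(
        _sample(("Description", "Found in Siberia, dated to 8000 BP")), LEX)
    assert f.geo_any and not f.geo_dedicated_field
    assert f.date_any and not f.date_dedicated_field


def test_coordinates_parsed_from_dedicated_fields():
    f = audit_sample_metadata(_sample(
        ("geographic location (latitude)", "52.2"),
        ("geographic location (longitude)", "0.12"),
    ), LEX)
    assert f.geo_coordinates
    assert (f.parsed_lat, f.parsed_lon) == pytest.approx((52.2, 0.12))


def test_unparseable_coordinates_do_not_count():
    f = audit_sample_metadata(_sample(
        ("geographic location (latitude)", "far north"),
        ("geographic location (longitude)", "0.12"),
    ), LEX)
    assert f.geo_any and not f.geo_coordinates
    assert any(e[0] == "geo_coordinates_unparseable" for e in f.evidence)


def test_lat_lon_combined_field_supported():
    f = audit_sample_metadata(_sample(("lat_lon", "52.2 N 0.12 E")), LEX)
    assert f.geo_coordinates


def test_c14_code_implies_dating_information():
    f = audit_sample_metadata(_sample(("Description", "OxA-12345")), LEX)
    assert f.date_any and f.c14_lab_code == "OxA-12345"


@pytest.mark.parametrize("attrs", [
    [("geographic location (region and locality)", "Iberia")],
    [("date", "2500 BCE")],
    [("tissue", "tooth")],
    [("Description", "Found in Mongolia; Bone; 4000 BP (Beta-123456)")],
    [("specimen voucher", "NHM-1"), ("lat_lon", "10 10")],
])
def test_dedicated_implies_any_and_evidence_nonempty(attrs):
    f = audit_sample_metadata(_sample(*attrs), LEX)
    f.check_invariants()
    for flag, dedicated in [(f.geo_any, f.geo_dedicated_field),
                            (f.date_any, f.date_dedicated_field),
                            (f.tissue_any, f.tissue_dedicated_field)]:
        assert flag or not dedicated
    fired = [f.geo_any, f.date_any, f.tissue_any, f.voucher_present]
    assert any(fired) and f.evidence


def test_findings_monotone_under_added_attributes():
    base = _sample(("Description", "Bone from Anatolia"))
    f1 = audit_sample_metadata(base, LEX)
    richer = _sample(("Description", "Bone from Anatolia"),
                     ("date", "4000 BP"),
                     ("specimen voucher", "V-9"))
    f2 = audit_sample_metadata(richer, LEX)
    for name in ("geo_any", "date_any", "tissue_any", "voucher_present",
                 "geo_dedicated_field", "tissue_dedicated_field"):
        assert (not getattr(f1, name)) or getattr(f2, name)


# ---------------------------------------------------------------------------
# experiment metadata


def _run(protocol=None, attrs=()):
    return RunRecord("RUNT1", "SAMT1", library_name="L1",
                     library_construction_protocol=protocol,
                     attributes=[Attribute(t, v) for t, v in attrs])


def test_protocol_keyword_detection():
    f = audit_experiment_metadata(_run("ss library, half-UDG"), LEX)
    assert f.library_protocol_present and "half-UDG" in f.protocol_keywords


def test_double_stranded_text_counts_as_protocol():
    f = audit_experiment_metadata(_run("double-stranded library"), LEX)
    assert f.library_protocol_present and "double-stranded" in f.protocol_keywords


def test_empty_protocol_and_no_keywords_is_absent():
    f = audit_experiment_metadata(_run(), LEX)
    assert not f.library_protocol_present and not f.protocol_keywords


def test_keyword_in_run_attribute_counts():
    f = audit_experiment_metadata(
        _run(attrs=[("library notes", "USER enzyme treated")]), LEX)
    assert f.library_protocol_present
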